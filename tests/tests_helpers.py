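"""Small helpers shared across test modules."""

import pandas as pd

from pmspline.logbook import annotate, build_design, clean_series


def build_from_dataset(dataset, fraction="PM2.5"):
    """Annotate every day of a synthetic campaign and build the design."""
    cfg = dataset.config
    frames = [annotate(clean_series(d.mass[fraction]), d.logbook)
              for d in dataset.days if fraction in d.mass]
    records = pd.concat(frames, ignore_index=True)
    return build_design(records, reference_station=cfg.stations[0],
                        reference_environment=cfg.environments[0])
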