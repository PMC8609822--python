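"""Bundled reference validation dataset.

Two small tables from an upright open-MRI validation session of the hip
clearance model: per-participant hip angles measured in the scanner and in
the motion-analysis laboratory at the matched motion frame, the least-squares
error (LSQE) between the two angle triples, the beta angle from the model
(MoLab) and measured directly in the scanner (MROpen), their absolute
difference, and participant BMI.

Angle sign conventions in the tables: positive flexion, positive internal
rotation, positive ABduction (note: abduction, not adduction).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_squat_reference", "load_fadir_reference"]


def _load(name: str) -> pd.DataFrame:
    with resources.files("hipclear.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_squat_reference() -> pd.DataFrame:
    """Squatting validation table (10 participants)."""
    return _load("squat_reference.csv")


def load_fadir_reference() -> pd.DataFrame:
    """Sitting FADIR validation table (7 participants)."""
    return _load("fadir_reference.csv")
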