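"""Coefficient-weighted aggregate risk scores for the held-out subsample.

For participant i the raw score is ``sum_j beta_j * x_ij`` over the
FDR-significant exposures, with the signed training-sample coefficients as
weights; exposures enter on the scale used in the screening fits.  The raw
score is then z-standardized within the scored subsample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exwas_engine import ExWASRecord

__all__ = ["ScoreVector", "compute_scores"]


@dataclass
class ScoreVector:
    participant_id: np.ndarray
    raw_score: np.ndarray
    z_score: np.ndarray
    n_components: int
    components: list[str] = field(default_factory=list)
    coefficients: dict[str, float] = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "participant_id": self.participant_id,
            "raw_score": self.raw_score,
            "z_score": self.z_score,
        })

    def metadata(self) -> dict:
        return {"n_components": self.n_components,
                "components": self.components,
                "coefficients": self.coefficients}


def compute_scores(test: pd.DataFrame, exwas: list[ExWASRecord]) -> ScoreVector:
    """Weighted sum of significant exposures, z-scored within the sample.

    Only records flagged both significant and converged contribute.  The test
    table must contain every contributing exposure with no missing values
    (i.e. already imputed).
    """
    if "subsample" in test.columns and (test["subsample"] == "train").any():
        test = test[test["subsample"] == "test"]
    used = [r for r in exwas if r.significant and r.converged]
    if not used:
        raise ValueError("no significant exposures: score undefined")
    missing = [r.exposure for r in used if r.exposure not in test.columns]
    if missing:
        raise ValueError(f"exposures absent from test table: {missing}")
    X = test[[r.exposure for r in used]]
    if X.isna().any().any():
        bad = list(X.columns[X.isna().any()])
        raise ValueError(f"missing exposure values (impute first): {bad}")
    betas = np.array([r.beta for r in used])
    raw = X.to_numpy(dtype=float) @ betas
    sd = raw.std(ddof=1)
    if sd == 0:
        raise ValueError("score is constant; cannot standardize")
    z = (raw - raw.mean()) / sd
    return ScoreVector(
        participant_id=test["participant_id"].to_numpy(),
        raw_score=raw,
        z_score=z,
        n_components=len(used),
        components=[r.exposure for r in used],
        coefficients={r.exposure: r.beta for r in used},
    )
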