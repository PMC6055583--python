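"""Omics-layer container and the matched three-grade sample design.

A study consists of three feature-by-sample matrices (methylation probes,
RNA, protein) over the same nine patients, each patient contributing one
sample per tissue grade: osteophytic cartilage, high-grade (damaged)
articular cartilage and low-grade (macroscopically intact) articular
cartilage.  Sample columns are labelled ``P{patient}_{grade}`` throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GRADES = ("osteophytic", "high", "low")

#: Contrast name -> (numerator grade, denominator grade).  A positive logFC
#: always means a higher value in the first-named tissue.
CONTRASTS = {
    "O_vs_L": ("osteophytic", "low"),
    "O_vs_H": ("osteophytic", "high"),
    "H_vs_L": ("high", "low"),
}

LAYERS = ("methylation", "rna", "protein")


class LayerError(ValueError):
    """Raised when a layer violates the matched-design invariants."""


def parse_sample_id(sample: str) -> tuple[str, str]:
    """Split ``P1_osteophytic`` into ``("P1", "osteophytic")``."""
    patient, _, grade = sample.rpartition("_")
    if grade not in GRADES or not patient:
        raise LayerError(
            f"sample id {sample!r} is not of the form 'P<i>_<grade>' "
            f"with grade in {GRADES}"
        )
    return patient, grade


def sample_id(patient: str, grade: str) -> str:
    return f"{patient}_{grade}"


@dataclass
class OmicsLayer:
    """One feature x sample matrix plus its sample design.

    Parameters
    ----------
    name
        One of ``methylation``, ``rna``, ``protein``.
    values
        DataFrame with feature IDs as index and ``P{i}_{grade}`` columns.
    scale
        How the values are to be read: ``raw`` (non-negative abundances),
        ``log`` (log2 scale), ``beta`` (methylation proportions in (0,1))
        or ``m`` (logit2 of beta).
    """

    name: str
    values: pd.DataFrame
    scale: str = "log"

    def __post_init__(self) -> None:
        if self.name not in LAYERS:
            raise LayerError(f"unknown layer name {self.name!r}")
        if self.scale not in ("raw", "log", "beta", "m"):
            raise LayerError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()][:3].tolist()
            raise LayerError(f"duplicate feature IDs, e.g. {dups}")
        # validates the sample-id format eagerly
        self.sample_design  # noqa: B018
        if self.scale == "beta":
            vals = self.values.to_numpy()
            finite = vals[np.isfinite(vals)]
            if finite.size and ((finite <= 0) | (finite >= 1)).any():
                raise LayerError("beta values must lie strictly in (0, 1)")

    @property
    def sample_design(self) -> pd.DataFrame:
        """(patient_id, grade) per sample column, in column order."""
        rows = [parse_sample_id(c) for c in self.values.columns]
        return pd.DataFrame(rows, columns=["patient", "grade"],
                            index=self.values.columns)

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def patients(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.values.columns:
            seen.setdefault(parse_sample_id(c)[0], None)
        return list(seen)

    def check_paired(self, grades: tuple[str, ...] = GRADES) -> None:
        """Every patient must be present in every requested grade."""
        design = self.sample_design
        for patient in self.patients:
            have = set(design.loc[design["patient"] == patient, "grade"])
            missing = [g for g in grades if g not in have]
            if missing:
                raise LayerError(
                    f"patient {patient!r} lacks grade(s) {missing} "
                    f"in layer {self.name!r}"
                )

    def grade_matrix(self, grade: str) -> pd.DataFrame:
        """Feature x patient matrix for one grade, patient-ordered."""
        cols = [sample_id(p, grade) for p in self.patients]
        missing = [c for c in cols if c not in self.values.columns]
        if missing:
            raise LayerError(f"missing samples {missing} in layer {self.name!r}")
        out = self.values[cols].copy()
        out.columns = self.patients
        return out

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "OmicsLayer":
        return OmicsLayer(self.name, values, scale or self.scale)

    # ---------------------------------------------------------------- I/O
    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature")

    @classmethod
    def from_tsv(cls, path: str | Path, name: str, scale: str = "log") -> "OmicsLayer":
        values = pd.read_csv(path, sep="\t", index_col="feature")
        return cls(name, values, scale)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, m = self.values.shape
        return f"<OmicsLayer {self.name}: {n} features x {m} samples ({self.scale})>"


def resolve_contrast(contrast: str | tuple[str, str]) -> tuple[str, str, str]:
    """Return ``(label, grade_a, grade_b)`` for a contrast name or grade pair."""
    if isinstance(contrast, str):
        if contrast not in CONTRASTS:
            raise LayerError(
                f"unknown contrast {contrast!r}; expected one of {sorted(CONTRASTS)}"
            )
        a, b = CONTRASTS[contrast]
        return contrast, a, b
    a, b = contrast
    for label, pair in CONTRASTS.items():
        if pair == (a, b):
            return label, a, b
    return f"{a}_vs_{b}", a, b
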