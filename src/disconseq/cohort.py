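"""Cohort container: an N-subjects x P-regions biomarker matrix with metadata.

The matrix holds regional structural-disconnectivity values (fractions in
[0, 1] when raw, arbitrary scale after log transform / covariate residualization),
one row per subject and one column per region, together with binary group
labels (0 = no/mild impairment analogue, 1 = moderate/severe analogue) and
optional age/sex covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_META_COLS = ("subject_id", "group", "age", "sex", "true_stage")


@dataclass
class Cohort:
    """Subjects x regions biomarker matrix plus per-subject metadata."""

    matrix: np.ndarray
    region_ids: list[str]
    subject_ids: list[str]
    group_labels: np.ndarray
    age: np.ndarray | None = None
    sex: np.ndarray | None = None
    true_stages: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.group_labels = np.asarray(self.group_labels, dtype=int)
        self.region_ids = [str(r) for r in self.region_ids]
        self.subject_ids = [str(s) for s in self.subject_ids]
        n, p = self.matrix.shape
        if len(self.region_ids) != p:
            raise ValueError(f"{len(self.region_ids)} region ids for {p} columns")
        if len(self.subject_ids) != n or len(self.group_labels) != n:
            raise ValueError("subject metadata length mismatch")
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicate subject ids")
        if np.isnan(self.matrix).any():
            raise ValueError("matrix contains missing cells")
        if not np.isin(self.group_labels, [0, 1]).all():
            raise ValueError("group labels must be 0/1")
        for name in ("age", "sex", "true_stages"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float if name == "age" else int)
                if len(v) != n:
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, v)

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.region_ids)
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "group", self.group_labels)
        if self.age is not None:
            df.insert(2, "age", self.age)
        if self.sex is not None:
            df.insert(3 if self.age is not None else 2, "sex", self.sex)
        if self.true_stages is not None:
            df["true_stage"] = self.true_stages
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "Cohort":
        df = pd.read_csv(path, sep="\t")
        region_cols = [c for c in df.columns if c not in _META_COLS]
        return cls(
            matrix=df[region_cols].to_numpy(float),
            region_ids=region_cols,
            subject_ids=df["subject_id"].astype(str).tolist(),
            group_labels=df["group"].to_numpy(int),
            age=df["age"].to_numpy(float) if "age" in df else None,
            sex=df["sex"].to_numpy(int) if "sex" in df else None,
            true_stages=df["true_stage"].to_numpy(int) if "true_stage" in df else None,
        )

    def with_matrix(self, matrix: np.ndarray, region_ids: list[str] | None = None) -> "Cohort":
        """Copy of this cohort with a replaced value matrix (same subjects)."""
        return Cohort(
            matrix=matrix,
            region_ids=self.region_ids if region_ids is None else region_ids,
            subject_ids=self.subject_ids,
            group_labels=self.group_labels,
            age=self.age,
            sex=self.sex,
            true_stages=self.true_stages,
        )
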