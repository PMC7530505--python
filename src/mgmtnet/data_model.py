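"""Dataset manifest, MGMT label derivation and case-level splitting.

Labels are derived from Illumina methylation-array beta-values: each case's
probe betas are averaged, and the cohort median of the per-case averages is
the cutoff (average strictly above the median -> methylated).  Splitting is
always at the case level so that no patient contributes slices to both the
training and the testing partition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, train_test_split

METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"
MODALITIES = ("CE-T1WI", "FLAIR")

__all__ = [
    "METHYLATED", "UNMETHYLATED", "MODALITIES",
    "CaseRecord", "DatasetManifest", "SplitAssignment",
    "derive_labels", "split_cases", "make_folds",
]


@dataclass
class CaseRecord:
    """One patient: ordered slice/mask references and an optional label."""

    case_id: str
    modality: str
    slice_refs: list[str]
    mask_refs: list[str]
    label: str | None = None
    beta_values: list[float] | None = None

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if len(self.slice_refs) != len(self.mask_refs) or not self.slice_refs:
            raise ValueError("slice_refs and mask_refs must be parallel, non-empty")
        if self.label is not None and self.label not in (METHYLATED, UNMETHYLATED):
            raise ValueError(f"unknown label {self.label!r}")
        if self.beta_values is not None:
            b = np.asarray(self.beta_values, dtype=float)
            if b.size == 0 or (b < 0).any() or (b > 1).any():
                raise ValueError("beta values must be non-empty and within [0, 1]")


@dataclass
class DatasetManifest:
    cases: list[CaseRecord]
    modality: str

    def __post_init__(self):
        ids = [c.case_id for c in self.cases]
        if len(set(ids)) != len(ids):
            raise ValueError("case_ids must be unique")
        for c in self.cases:
            if c.modality != self.modality:
                raise ValueError("manifest must hold a single modality")

    def __len__(self):
        return len(self.cases)

    def case(self, case_id: str) -> CaseRecord:
        for c in self.cases:
            if c.case_id == case_id:
                return c
        raise KeyError(case_id)

    @property
    def labels(self) -> dict[str, str | None]:
        return {c.case_id: c.label for c in self.cases}

    # ------------------------------------------------------------- CSV I/O
    def to_csv(self, path) -> None:
        rows = []
        for c in self.cases:
            betas = ";".join(f"{b:g}" for b in c.beta_values) if c.beta_values else ""
            for s, m in zip(c.slice_refs, c.mask_refs):
                rows.append({"case_id": c.case_id, "modality": c.modality,
                             "slice_path": s, "mask_path": m,
                             "label": c.label or "", "beta_values": betas})
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DatasetManifest":
        df = pd.read_csv(path, dtype=str).fillna("")
        cases = []
        for cid, grp in df.groupby("case_id", sort=False):
            betas = grp["beta_values"].iloc[0]
            cases.append(CaseRecord(
                case_id=str(cid),
                modality=grp["modality"].iloc[0],
                slice_refs=list(grp["slice_path"]),
                mask_refs=list(grp["mask_path"]),
                label=grp["label"].iloc[0] or None,
                beta_values=[float(x) for x in betas.split(";")] if betas else None,
            ))
        return cls(cases=cases, modality=cases[0].modality)


@dataclass
class SplitAssignment:
    """Case-level train/test split with optional k-fold partition of train."""

    train_ids: list[str]
    test_ids: list[str]
    folds: list[list[str]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")
        if self.folds:
            self._check_folds()

    def _check_folds(self):
        flat = [i for f in self.folds for i in f]
        if len(flat) != len(set(flat)) or set(flat) != set(self.train_ids):
            raise ValueError("folds must partition train_ids")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"train_ids": list(self.train_ids),
                       "test_ids": list(self.test_ids),
                       "folds": [list(f) for f in self.folds],
                       "seed": self.seed}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SplitAssignment":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def derive_labels(beta_values_per_case: dict[str, list[float]]) -> dict[str, str]:
    """Median-cutoff methylation call from per-case probe beta-values.

    Probe betas within a case are combined by arithmetic mean; the cohort
    median of per-case means is the cutoff; a mean strictly above the cutoff
    is called methylated, otherwise unmethylated (ties -> unmethylated).
    """
    if not beta_values_per_case:
        raise ValueError("empty cohort")
    means = {}
    for cid, betas in beta_values_per_case.items():
        b = np.asarray(betas, dtype=float)
        if b.size == 0:
            raise ValueError(f"case {cid}: empty beta list")
        if (b < 0).any() or (b > 1).any():
            raise ValueError(f"case {cid}: beta values outside [0, 1]")
        means[cid] = float(b.mean())
    cutoff = float(np.median(sorted(means.values())))
    return {cid: (METHYLATED if m > cutoff else UNMETHYLATED)
            for cid, m in means.items()}


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def split_cases(manifest: DatasetManifest, test_fraction: float = 0.2,
                seed: int = 0) -> SplitAssignment:
    """Case-level random split; |test| = round(test_fraction * n).

    Stratified by label when both classes are present (so small cohorts keep
    both classes in each partition); otherwise a plain shuffle split.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    n = len(manifest)
    if n < 2:
        raise ValueError("need at least 2 cases to split")
    n_test = _round_half_away(test_fraction * n)
    if n_test < 1 or n_test >= n:
        raise ValueError(f"test fraction {test_fraction} gives an empty partition for n={n}")
    ids = [c.case_id for c in manifest.cases]
    labels = [c.label for c in manifest.cases]
    stratify = labels if (all(l is not None for l in labels)
                          and len(set(labels)) > 1
                          and min(labels.count(l) for l in set(labels)) >= 2
                          and n_test >= len(set(labels))) else None
    train, test = train_test_split(ids, test_size=n_test, random_state=seed,
                                   shuffle=True, stratify=stratify)
    return SplitAssignment(train_ids=sorted(train), test_ids=sorted(test), seed=seed)


def make_folds(split: SplitAssignment, k: int = 10, seed: int = 0) -> SplitAssignment:
    """Partition the training cases into k folds of near-equal size."""
    ids = sorted(split.train_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds number of training cases ({len(ids)})")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [[ids[i] for i in val_idx] for _, val_idx in kf.split(ids)]
    return SplitAssignment(train_ids=split.train_ids, test_ids=split.test_ids,
                           folds=folds, seed=seed)
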