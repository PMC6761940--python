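"""Data preparation for pharmacogenomic perturbation modeling.

The pipeline mirrors how short-term drug-perturbation screens (L1000-style
case/control experiments) are combined with cell-line viability screens:

1. match DMSO vehicle controls to treatment profiles by batch and bead ID;
2. drop case-control pairs whose profiles correlate poorly (Pearson rho
   below a threshold, default 0.75) — likely mislabeled wells or outliers;
3. standardize every gene to zero mean / unit variance on the training rows;
4. remove the first principal component of the pooled standardized data
   (coarse batch/source-effect removal);
5. binarize continuous drug sensitivity (AAC, area above the dose-response
   curve) per drug with the waterfall method;
6. keep drugs with enough perturbed cell lines and a sensitive fraction
   above a floor.

All fitted transforms store their training provenance and refuse to apply
to data with a different gene set, so no test-fold statistics can leak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gaussian import DimensionError, ValidationError

PAIR_MANIFEST_COLUMNS = [
    "drug_id", "cell_line_id", "control_sample", "treated_sample",
    "batch_id", "bead_id", "concentration", "duration_h",
]
SENSITIVITY_COLUMNS = ["drug_id", "cell_line_id", "aac"]


@dataclass
class PerturbationPair:
    """Matched control / treated expression with experiment metadata."""

    drug_id: str
    cell_line_id: str
    x1: np.ndarray
    x2: np.ndarray
    batch_id: str
    bead_id: str
    concentration: float = 1e-6
    duration_h: float = 6.0
    y: Optional[int] = None

    def __post_init__(self) -> None:
        self.x1 = np.asarray(self.x1, dtype=float)
        self.x2 = np.asarray(self.x2, dtype=float)
        if self.x1.shape != self.x2.shape:
            raise DimensionError("x1 and x2 lengths differ")
        if not self.duration_h > 0:
            raise ValidationError("duration_h must be positive")
        if not self.concentration > 0:
            raise ValidationError("concentration must be positive")
        if self.y is not None and self.y not in (0, 1):
            raise ValidationError("y must be 0, 1 or None")


@dataclass
class DoseResponseRecord:
    """Continuous sensitivity of one cell line to one drug."""

    drug_id: str
    cell_line_id: str
    aac: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.aac <= 1.0:
            raise ValidationError(f"AAC must lie in [0, 1], got {self.aac}")


# ---------------------------------------------------------------------------
# pair matching
# ---------------------------------------------------------------------------

def match_case_control(controls: Sequence[dict], treatments: Sequence[dict]):
    """Pair each treatment with a vehicle control sharing (batch_id, bead_id).

    ``controls`` and ``treatments`` are sequences of dicts with at least
    ``batch_id``, ``bead_id`` and ``expression``; treatments additionally
    carry ``drug_id`` and ``cell_line_id``.  One control may serve several
    treatments.  Returns ``(pairs, unmatched_treatments)``.
    """
    for name, records in (("control", controls), ("treatment", treatments)):
        missing = [i for i, r in enumerate(records)
                   if "batch_id" not in r or "bead_id" not in r]
        if missing:
            raise ValidationError(
                f"{name} records missing batch_id/bead_id at indices {missing}")
    by_key: dict = {}
    for c in controls:
        # first control wins for a duplicated key; it may serve many treatments
        by_key.setdefault((c["batch_id"], c["bead_id"]), c)
    pairs, unmatched = [], []
    for t in treatments:
        key = (t["batch_id"], t["bead_id"])
        c = by_key.get(key)
        if c is None:
            unmatched.append(t)
            continue
        pairs.append(PerturbationPair(
            drug_id=t.get("drug_id", ""),
            cell_line_id=t.get("cell_line_id", ""),
            x1=c["expression"], x2=t["expression"],
            batch_id=t["batch_id"], bead_id=t["bead_id"],
            concentration=t.get("concentration", 1e-6),
            duration_h=t.get("duration_h", 6.0),
            y=t.get("y"),
        ))
    return pairs, unmatched


def select_concentration(concentrations: Sequence[float]) -> float:
    """The most common tested concentration; ties go to the lower value."""
    vals, counts = np.unique(np.asarray(concentrations, dtype=float),
                             return_counts=True)
    return float(vals[counts == counts.max()].min())


def closest_concentration(target: float, tested: Sequence[float]) -> float:
    """Nearest tested concentration by absolute log10 distance."""
    tested = np.asarray(tested, dtype=float)
    return float(tested[np.argmin(np.abs(np.log10(tested) - np.log10(target)))])


def filter_pairs_by_correlation(pairs: Sequence[PerturbationPair],
                                threshold: float = 0.75):
    """Keep pairs with Pearson correlation(x1, x2) strictly above ``threshold``.

    Zero-variance profiles are rejected with reason ``"degenerate"`` rather
    than raising.  Returns ``(retained, rejected)`` where rejected entries
    are ``(pair, reason)`` tuples.
    """
    retained, rejected = [], []
    for p in pairs:
        if p.x1.size < 3:
            raise ValidationError("profiles must have length >= 3")
        if np.std(p.x1) == 0.0 or np.std(p.x2) == 0.0:
            rejected.append((p, "degenerate"))
            continue
        rho = float(stats.pearsonr(p.x1, p.x2).statistic)
        if rho > threshold:
            retained.append(p)
        else:
            rejected.append((p, f"correlation {rho:.4f} <= {threshold}"))
    return retained, rejected


# ---------------------------------------------------------------------------
# fitted, leakage-safe transforms
# ---------------------------------------------------------------------------

@dataclass
class GeneStandardizer:
    """Per-gene location/scale fit on training rows, applied everywhere.

    Uses the population variance convention (divide by n).  Constant genes
    are flagged and their scale clamped to 1 so they are centered only.
    """

    mean_: np.ndarray = field(default=None, repr=False)
    scale_: np.ndarray = field(default=None, repr=False)
    constant_genes_: np.ndarray = field(default=None, repr=False)
    n_fit_rows_: int = 0
    variance_convention: str = "population"

    def fit(self, matrix: np.ndarray, fit_on: Optional[Sequence[int]] = None):
        matrix = np.asarray(matrix, dtype=float)
        rows = matrix if fit_on is None else matrix[np.asarray(fit_on, dtype=int)]
        if rows.shape[0] == 0:
            raise ValidationError("fit_on selects no rows")
        self.mean_ = rows.mean(axis=0)
        var = rows.var(axis=0)  # population (ddof=0)
        self.constant_genes_ = var == 0.0
        scale = np.sqrt(var)
        scale[self.constant_genes_] = 1.0
        self.scale_ = scale
        self.n_fit_rows_ = rows.shape[0]
        return self

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise ValidationError("GeneStandardizer not fitted")
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape[1] != self.mean_.shape[0]:
            raise DimensionError(
                f"gene count {matrix.shape[1]} != fitted {self.mean_.shape[0]}")
        return (matrix - self.mean_) / self.scale_

    def fit_transform(self, matrix, fit_on=None):
        return self.fit(matrix, fit_on).transform(matrix)


def standardize_genes(matrix: np.ndarray, fit_on: Optional[Sequence[int]] = None):
    """Standardize each gene to zero mean / unit variance on ``fit_on`` rows.

    Returns ``(standardized_matrix, GeneStandardizer)``; the transform is
    estimated on the training rows only and applied to all rows."""
    st = GeneStandardizer()
    return st.fit_transform(matrix, fit_on), st


@dataclass
class FirstPCRemover:
    """Removes the leading principal axis fit on pooled training rows.

    Expects already-standardized input.  The stored axis ``component_`` is
    reused on held-out rows; re-application is a no-op in the deflated
    subspace."""

    component_: np.ndarray = field(default=None, repr=False)
    explained_variance_ratio_: float = float("nan")
    n_fit_rows_: int = 0

    def fit(self, matrix: np.ndarray, fit_on: Optional[Sequence[int]] = None):
        matrix = np.asarray(matrix, dtype=float)
        rows = matrix if fit_on is None else matrix[np.asarray(fit_on)]
        if rows.shape[0] < 2:
            raise ValidationError("need at least 2 rows to fit a principal axis")
        centered = rows - rows.mean(axis=0)
        if not np.any(centered):
            raise ValidationError("rank-0 input: no variation to decompose")
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        self.component_ = vt[0]
        self.explained_variance_ratio_ = float(s[0] ** 2 / np.sum(s ** 2))
        self.n_fit_rows_ = rows.shape[0]
        return self

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        if self.component_ is None:
            raise ValidationError("FirstPCRemover not fitted")
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape[1] != self.component_.shape[0]:
            raise DimensionError(
                f"gene count {matrix.shape[1]} != fitted {self.component_.shape[0]}")
        v = self.component_
        return matrix - np.outer(matrix @ v, v)

    def fit_transform(self, matrix, fit_on=None):
        return self.fit(matrix, fit_on).transform(matrix)


def remove_first_pc(matrix: np.ndarray, fit_on: Optional[Sequence[int]] = None):
    """Deflate the first principal component (fit on ``fit_on`` rows).

    Returns ``(deflated_matrix, FirstPCRemover)``."""
    pc = FirstPCRemover()
    return pc.fit_transform(matrix, fit_on), pc


# ---------------------------------------------------------------------------
# waterfall binarization and drug selection
# ---------------------------------------------------------------------------

def waterfall_binarize(records: Sequence[DoseResponseRecord],
                       linearity_threshold: float = 0.95,
                       linear_branch: str = "median"):
    """Binarize continuous AAC values for one drug by the waterfall method.

    The AAC values are sorted in descending order.  If the sorted curve is
    close to linear in rank (Pearson correlation with its linear fit at or
    above ``linearity_threshold``), the cutoff is the median AAC; otherwise
    the cutoff sits at the point of maximum perpendicular distance from the
    chord joining the first and last sorted points (the "elbow").  Cell
    lines with AAC strictly above the cutoff are labeled sensitive; ties at
    the cutoff go to non-sensitive.

    Returns ``(labels, cutoff)`` with ``labels`` a dict keyed by cell line.
    """
    if len(records) < 3:
        raise ValidationError("waterfall binarization needs at least 3 cell lines")
    aac = np.array([r.aac for r in records], dtype=float)
    if np.unique(aac).size < 2:
        raise ValidationError("waterfall binarization needs distinct AAC values")
    order = np.argsort(-aac, kind="stable")
    sorted_aac = aac[order]
    ranks = np.arange(len(sorted_aac), dtype=float)

    rho = float(stats.pearsonr(ranks, sorted_aac).statistic)
    linearity = abs(rho)
    if linearity >= linearity_threshold and linear_branch == "median":
        cutoff = float(np.median(aac))
    else:
        cutoff = float(sorted_aac[_max_chord_distance_index(ranks, sorted_aac)])

    labels = {r.cell_line_id: int(r.aac > cutoff) for r in records}
    return labels, cutoff


def _max_chord_distance_index(x: np.ndarray, y: np.ndarray) -> int:
    """Index of the point farthest (perpendicular) from the first-last chord."""
    p0 = np.array([x[0], y[0]])
    p1 = np.array([x[-1], y[-1]])
    chord = p1 - p0
    norm = np.hypot(*chord)
    pts = np.stack([x, y], axis=1) - p0
    dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0]) / norm
    return int(np.argmax(dist))


def select_drugs(pair_cell_lines: dict, labels: dict,
                 min_cell_lines: int = 8, min_sensitive_frac: float = 0.20):
    """Retain drugs with enough perturbed cell lines and enough responders.

    ``pair_cell_lines`` maps drug -> iterable of cell lines with perturbation
    pairs; ``labels`` maps drug -> {cell_line: 0/1} binarized sensitivity.
    A drug is kept when (i) it has at least ``min_cell_lines`` distinct
    perturbed cell lines and (ii) at least ``min_sensitive_frac`` of its
    screened cell lines are sensitive.  Returns ``(retained, report)`` where
    the report lists the per-drug counts and fractions.
    """
    retained, report = [], {}
    for drug in sorted(set(pair_cell_lines) | set(labels)):
        n_cls = len(set(pair_cell_lines.get(drug, ())))
        drug_labels = labels.get(drug, {})
        frac = (sum(drug_labels.values()) / len(drug_labels)) if drug_labels else 0.0
        keep = n_cls >= min_cell_lines and frac >= min_sensitive_frac
        report[drug] = {"n_pair_cell_lines": n_cls, "sensitive_frac": frac,
                        "retained": keep}
        if keep:
            retained.append(drug)
    return retained, report


# ---------------------------------------------------------------------------
# file formats (TSV expression matrices, CSV manifests)
# ---------------------------------------------------------------------------

def read_expression_tsv(path) -> pd.DataFrame:
    """Samples x genes matrix: first row gene identifiers, first column
    sample identifiers, tab-separated."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_pair_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PAIR_MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"pair manifest missing columns: {missing}")
    return df


def read_sensitivity_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SENSITIVITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"sensitivity table missing columns: {missing}")
    return df
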