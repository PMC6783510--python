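"""Expression matrices, differential scoring, and ranked gene lists.

This module turns a normalized (log-scale) expression matrix with
treatment/control sample labels into a ranked gene list: every measured
gene ordered by a treatment-vs-control differential-expression score.
Ranked lists are the sole input the enrichment machinery sees, so the
ordering rule (score descending, ties broken by gene id) is fixed here
and is deterministic across platforms.

Three rank metrics are provided:

``log_fold_change``
    Mean(treatment) − mean(control). On log-scale intensities this is a
    log fold change. Works with a single replicate per group.
``t_statistic``
    Pooled-variance two-sample t. Requires two replicates per group.
``moderated_t`` (default)
    The pooled t with the gene-wise variance shrunk toward a common
    prior: posterior variance = (d0·s0² + df·s²) / (d0 + df), with the
    prior degrees of freedom d0 and prior variance s0² estimated by a
    method-of-moments fit of a scaled-F marginal to the observed
    gene-wise variances. With few replicates per group this stabilises
    the denominator the same way empirical-Bayes moderated statistics
    do, while keeping the package self-contained.

File formats: GCT v1.2 and plain TSV for matrices, CLS for sample
labels, RNK (2-column TSV) for ranked lists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "RankedGeneList",
    "load_expression_matrix",
    "read_cls",
    "differential_scores",
    "build_ranked_list",
    "read_rnk",
    "write_rnk",
]

GROUPS = ("treatment", "control")


@dataclass
class ExpressionMatrix:
    """Genes × samples matrix of normalized log-scale intensities.

    Parameters
    ----------
    data
        DataFrame indexed by gene id, one column per sample. Values must
        be finite floats.
    sample_groups
        Mapping sample id → ``"treatment"`` or ``"control"``; every
        column of ``data`` must be labeled and each group must contain
        at least one sample.
    """

    data: pd.DataFrame
    sample_groups: Mapping[str, str]

    def __post_init__(self) -> None:
        idx = self.data.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate gene id in matrix: {dup!r}")
        cols = self.data.columns
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate sample id in matrix: {dup!r}")
        unlabeled = [s for s in cols if s not in self.sample_groups]
        if unlabeled:
            raise ValueError(f"unlabeled sample(s): {unlabeled}")
        bad = {s: g for s, g in self.sample_groups.items() if g not in GROUPS}
        if bad:
            raise ValueError(f"sample group must be one of {GROUPS}, got {bad}")
        for g in GROUPS:
            if not any(self.sample_groups[s] == g for s in cols):
                raise ValueError(f"no sample labeled {g!r}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("matrix contains non-numeric values")
        if not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at gene {idx[i]!r}, sample {cols[j]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def group_columns(self, group: str) -> list[str]:
        return [s for s in self.data.columns if self.sample_groups[s] == group]


@dataclass(frozen=True)
class RankedGeneList:
    """Genes ordered by differential-expression score, descending.

    ``entries`` is the ordered sequence of ``(gene_id, score)`` pairs.
    The order is strictly (score descending, gene id ascending on ties);
    the constructor validates rather than re-sorts, so a list built by
    :func:`build_ranked_list` round-trips unchanged.
    """

    entries: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if len(self.entries) < 2:
            raise ValueError("a ranked list needs at least 2 genes")
        genes = [g for g, _ in self.entries]
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene id in ranked list")
        scores = [s for _, s in self.entries]
        if not all(math.isfinite(s) for s in scores):
            raise ValueError("non-finite score in ranked list")
        for (g1, s1), (g2, s2) in zip(self.entries, self.entries[1:]):
            if s1 < s2 or (s1 == s2 and g1 > g2):
                raise ValueError(
                    "ranked list order violated between "
                    f"({g1}, {s1}) and ({g2}, {s2})"
                )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.entries)

    @property
    def scores(self) -> np.ndarray:
        return np.array([s for _, s in self.entries], dtype=float)


def _read_tsv_matrix(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return _coerce_numeric(df, path)


def _read_gct_matrix(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().rstrip("\n")
        if version != "#1.2":
            raise ValueError(f"{path}: expected GCT header '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise ValueError(f"{path}: malformed GCT dimensions line")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        body = pd.read_csv(fh, sep="\t", dtype=str)
    if body.shape[0] != n_genes or body.shape[1] - 2 != n_samples:
        raise ValueError(
            f"{path}: GCT dimensions line says {n_genes}×{n_samples} but body has "
            f"{body.shape[0]}×{body.shape[1] - 2}"
        )
    body = body.set_index(body.columns[0])
    body = body.drop(columns=body.columns[0])  # Description column
    return _coerce_numeric(body, path)


def _coerce_numeric(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    raw_na = df.isna().to_numpy()
    bad = out.isna().to_numpy() & ~raw_na
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: non-numeric cell {df.iat[i, j]!r} at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    return out


def read_cls(path: str | Path, label_map: Mapping[str, str] | None = None) -> dict[str, str]:
    """Read a 3-line categorical CLS file into a per-position group list.

    Returns a mapping from 0-based sample position (as managed by
    :func:`load_expression_matrix`) — concretely a dict
    ``{position_index: group}``. Class names must identify the
    treatment/control dichotomy, either literally or via ``label_map``
    (e.g. ``{"vehicle": "control", "drug": "treatment"}``).
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) < 3:
        raise ValueError(f"{path}: CLS file needs 3 lines")
    header = lines[0].split()
    n_samples, n_classes = int(header[0]), int(header[1])
    names = lines[1].lstrip("#").split()
    if len(names) != n_classes:
        raise ValueError(f"{path}: CLS declares {n_classes} classes, names line has {len(names)}")
    assignments = lines[2].split()
    if len(assignments) != n_samples:
        raise ValueError(
            f"{path}: CLS declares {n_samples} samples, assignment line has {len(assignments)}"
        )

    def canon(name: str) -> str:
        if label_map and name in label_map:
            name = label_map[name]
        low = name.lower()
        if low in GROUPS:
            return low
        raise ValueError(
            f"{path}: cannot map CLS class {name!r} to treatment/control; "
            "pass label_map"
        )

    groups = {}
    for pos, token in enumerate(assignments):
        if token in names:
            cls = token
        else:
            cls = names[int(token)]
        groups[pos] = canon(cls)
    return groups


def load_expression_matrix(
    path: str | Path,
    format: str | None = None,
    labels: str | Path | Mapping[str, str] | None = None,
    label_map: Mapping[str, str] | None = None,
    impute_missing: bool = False,
) -> ExpressionMatrix:
    """Load a GCT or TSV expression matrix with sample group labels.

    ``labels`` is either a CLS file path (positional assignment in file
    column order) or a mapping sample id → group. Missing values are
    rejected unless ``impute_missing`` is set, in which case they are
    replaced by the gene's row mean (the imputation count is reported in
    the raised log record).
    """
    import logging

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "gct":
        df = _read_gct_matrix(path)
    elif format == "tsv":
        df = _read_tsv_matrix(path)
    else:
        raise ValueError(f"unknown matrix format {format!r}")

    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene row {dup!r}")

    if df.isna().to_numpy().any():
        if not impute_missing:
            i, j = np.argwhere(df.isna().to_numpy())[0]
            raise ValueError(
                f"{path}: missing value at gene {df.index[i]!r}, sample "
                f"{df.columns[j]!r} (set impute_missing=True to use row means)"
            )
        n = int(df.isna().to_numpy().sum())
        df = df.apply(lambda row: row.fillna(row.mean()), axis=1)
        logging.getLogger(__name__).info("imputed %d missing values with row means", n)

    if labels is None:
        raise ValueError("sample labels are required (CLS path or mapping)")
    if isinstance(labels, (str, Path)):
        by_pos = read_cls(labels, label_map=label_map)
        if len(by_pos) != df.shape[1]:
            raise ValueError(
                f"CLS labels {len(by_pos)} samples but matrix has {df.shape[1]}"
            )
        groups = {df.columns[pos]: g for pos, g in by_pos.items()}
    else:
        groups = dict(labels)
    return ExpressionMatrix(data=df.astype(float), sample_groups=groups)


def _fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F variance marginal.

    Under the hierarchical model s² | σ² ~ σ²·χ²_df/df with
    σ² ~ d0·s0²/χ²_d0, the marginal of s² is s0²·F(df, d0). Matching the
    first two moments over genes gives d0 and s0². Degenerate fits
    (moment ratio incompatible with finite d0) fall back to complete
    shrinkage: d0 = ∞, s0² = mean(s²).
    """
    m = float(np.mean(s2))
    v = float(np.var(s2, ddof=1)) if s2.size > 1 else 0.0
    if m <= 0 or v <= 0:
        return math.inf, m
    r = v / m**2
    denom = r * df - 2.0
    if denom <= 0:
        return math.inf, m
    d0 = (4.0 * r * df + 2.0 * df - 4.0) / denom
    if d0 <= 2.0 or not math.isfinite(d0):
        return math.inf, m
    s0_sq = m * (d0 - 2.0) / d0
    return d0, s0_sq


def differential_scores(
    matrix: ExpressionMatrix,
    method: str = "moderated_t",
    variance_floor: float | None = None,
) -> dict[str, float]:
    """Per-gene treatment-vs-control scores; positive = up in treatment.

    ``variance_floor`` (optional) is added to the pooled variance for the
    t-based methods, guarding against zero-variance genes on nearly
    discrete data.
    """
    t_cols = matrix.group_columns("treatment")
    c_cols = matrix.group_columns("control")
    x_t = matrix.data[t_cols].to_numpy(dtype=float)
    x_c = matrix.data[c_cols].to_numpy(dtype=float)
    n_t, n_c = x_t.shape[1], x_c.shape[1]
    delta = x_t.mean(axis=1) - x_c.mean(axis=1)

    if method == "log_fold_change":
        scores = delta
    elif method in ("t_statistic", "moderated_t"):
        if n_t < 2 or n_c < 2:
            raise ValueError(f"{method} needs ≥2 samples per group (got {n_t}, {n_c})")
        df = n_t + n_c - 2
        ss = x_t.var(axis=1, ddof=1) * (n_t - 1) + x_c.var(axis=1, ddof=1) * (n_c - 1)
        s2 = ss / df
        if variance_floor is not None:
            s2 = s2 + variance_floor
        if method == "moderated_t":
            d0, s0_sq = _fit_variance_prior(s2, df)
            if math.isinf(d0):
                s2_post = np.full_like(s2, s0_sq)
            else:
                s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        else:
            s2_post = s2
        if np.all(s2_post == 0):
            raise ValueError(
                "zero within-group variance for all genes; use moderated_t or "
                "set variance_floor"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = delta / np.sqrt(s2_post * (1.0 / n_t + 1.0 / n_c))
        scores = np.where(np.isfinite(scores), scores, 0.0)
    else:
        raise ValueError(f"unknown method {method!r}")

    return {g: float(s) for g, s in zip(matrix.gene_ids, scores)}


def build_ranked_list(scores: Mapping[str, float]) -> RankedGeneList:
    """Order genes by score descending, exact ties by gene id ascending."""
    if len(scores) < 2:
        raise ValueError("need at least 2 genes to build a ranked list")
    for g, s in scores.items():
        if not math.isfinite(s):
            raise ValueError(f"non-finite score for gene {g!r}")
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return RankedGeneList(entries=tuple((g, float(s)) for g, s in ordered))


def write_rnk(ranked: RankedGeneList, path: str | Path) -> None:
    """Export as RNK-compatible 2-column TSV (gene, score)."""
    with open(path, "w") as fh:
        for g, s in ranked.entries:
            fh.write(f"{g}\t{s!r}\n")


def read_rnk(path: str | Path) -> RankedGeneList:
    """Read a 2-column gene/score TSV (no header) and re-rank it."""
    scores: dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
        gene, score = parts
        if gene in scores:
            raise ValueError(f"{path}:{lineno}: duplicate gene {gene!r}")
        scores[gene] = float(score)
    return build_ranked_list(scores)
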