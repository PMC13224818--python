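"""Tissue expression bias: relative expression, 2-fold bias labels at gene
and superfamily level, cross-species conservation categories, per-species
bias census, PCA variance summary, and the capped heatmap matrix.

A gene (or superfamily) is *biased* toward a tissue when its mean expression
there is at least ``fold`` (default 2) times its mean in every other tissue;
otherwise it is *neutral*.  The rule is scale-invariant, so it may equally be
applied to relative expression (each tissue's mean divided by the gene's
total across tissues).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, SpeciesConfig, TISSUES

logger = logging.getLogger(__name__)

__all__ = [
    "TissueProfile",
    "BIAS_LABELS",
    "tissue_profile",
    "gene_bias",
    "family_bias",
    "assign_category",
    "bias_census",
    "pca_variance",
    "heatmap_matrix",
]

#: The five possible bias labels.  "NA" marks absent or all-zero data.
BIAS_LABELS = ("nodule", "root", "shoot", "neutral", "NA")


@dataclass
class TissueProfile:
    """Per-tissue mean expression and relative expression for one gene.

    ``rel_expr`` holds each tissue's share of the gene's summed tissue means
    (NaN throughout when the total is zero); ``sem`` the standard error of
    the mean per tissue.
    """

    gene_id: str
    mean_expr: dict[str, float]
    rel_expr: dict[str, float]
    sem: dict[str, float]

    @property
    def is_na(self) -> bool:
        return all(math.isnan(v) for v in self.rel_expr.values())


def tissue_profile(matrix: ExpressionMatrix, gene: str) -> TissueProfile:
    """Mean, standard error and relative expression per tissue for one gene
    (replicates averaged within tissue)."""
    if gene not in matrix.genes:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    means: dict[str, float] = {}
    sems: dict[str, float] = {}
    for tissue in TISSUES:
        cols = matrix.samples_for(tissue)
        if not cols:
            means[tissue] = float("nan")
            sems[tissue] = float("nan")
            continue
        vals = matrix.values.loc[gene, cols].to_numpy(dtype=float)
        means[tissue] = float(vals.mean())
        sems[tissue] = (
            float(vals.std(ddof=1) / math.sqrt(len(vals)))
            if len(vals) > 1 else 0.0
        )
    total = math.fsum(v for v in means.values() if not math.isnan(v))
    if total > 0:
        rel = {
            t: (means[t] / total if not math.isnan(means[t]) else float("nan"))
            for t in TISSUES
        }
    else:
        rel = {t: float("nan") for t in TISSUES}
    return TissueProfile(gene, means, rel, sems)


def _fold_label(means: dict[str, float], fold: float) -> str:
    vals = {t: v for t, v in means.items() if not math.isnan(v)}
    if not vals or all(v == 0 for v in vals.values()):
        return "NA"
    top_tissue = max(vals, key=lambda t: (vals[t], -TISSUES.index(t)))
    top = vals[top_tissue]
    others = [v for t, v in vals.items() if t != top_tissue]
    if all(top >= fold * v for v in others) and not any(
        v == top for v in others
    ):
        return top_tissue
    return "neutral"


def gene_bias(profile: TissueProfile, fold: float = 2.0) -> str:
    """2-fold bias label for one gene: the top tissue if its mean is at
    least ``fold`` times each other tissue's mean, else ``neutral``
    (``NA`` when the profile has no data)."""
    return _fold_label(profile.mean_expr, fold)


def family_bias(
    matrix: ExpressionMatrix, members: list[str], fold: float = 2.0
) -> str:
    """Superfamily-level bias: average the tissue means of all member genes
    (unweighted), then apply the same >= ``fold`` rule."""
    present = [g for g in members if g in matrix.genes]
    if not present:
        return "NA"
    tm = matrix.tissue_means().loc[present]
    means = {t: float(tm[t].mean()) for t in TISSUES}
    return _fold_label(means, fold)


def assign_category(
    labels: dict[str, str], config: SpeciesConfig
) -> int:
    """Cross-species conservation category (1-5) from per-species bias
    labels.

    With P the labels of the configured PAP species and c the CAE label:

    5. c or any PAP label is NA, or all labels are neutral.
    1. PAP labels all equal and non-neutral, c equal to them.
    2. PAP labels all equal and non-neutral, c different.
    3. otherwise (PAP consensus absent), c non-neutral and matching at
       least one PAP label.
    4. otherwise.

    An all-neutral PAP consensus with a non-neutral CAE label falls through
    to 3/4 (there is no non-neutral PAP pattern to be "conserved within"),
    yielding 4 since a neutral PAP label cannot match a non-neutral c.
    """
    def get(code: str) -> str:
        if code not in labels:
            logger.warning("no bias label for %s; treated as NA", code)
            return "NA"
        return labels[code]

    pap = [get(code) for code in sorted(config.pap_set)]
    cae = get(config.cae_code)
    if cae == "NA" or "NA" in pap:
        return 5
    if all(lbl == "neutral" for lbl in pap + [cae]):
        return 5
    if len(set(pap)) == 1 and pap[0] != "neutral":
        return 1 if cae == pap[0] else 2
    if cae != "neutral" and cae in pap:
        return 3
    return 4


def bias_census(
    labels: dict[str, dict[str, str]],
) -> pd.DataFrame:
    """Counts of superfamilies per bias label per species.

    ``labels`` maps superfamily_id -> species code -> label.  Rows are
    species, columns the five labels; each row sums to the number of
    superfamilies with an entry for that species.
    """
    counts: dict[str, dict[str, int]] = {}
    for fam_labels in labels.values():
        for sp, lbl in fam_labels.items():
            row = counts.setdefault(sp, {l: 0 for l in BIAS_LABELS})
            row[lbl] += 1
    df = pd.DataFrame.from_dict(counts, orient="index").fillna(0).astype(int)
    return df.reindex(columns=list(BIAS_LABELS), fill_value=0).sort_index()


def pca_variance(features: pd.DataFrame) -> np.ndarray:
    """Fractions of variance explained by the principal components of a
    superfamilies x features table of relative expression.

    Columns are centered and scaled to unit variance; constant columns are
    dropped with a warning.  Fractions are computed from the singular values
    of the standardized matrix, in descending order; they sum to 1 over the
    full rank.
    """
    X = features.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError(
            "PCA input contains missing values; restrict to complete cases"
        )
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = list(features.columns[~keep])
        logger.warning("dropping constant column(s) from PCA: %s", dropped)
        X = X[:, keep]
        sd = sd[keep]
    if X.shape[1] == 0:
        raise ValueError("no non-constant columns for PCA")
    Z = (X - X.mean(axis=0)) / sd
    s = np.linalg.svd(Z, compute_uv=False)
    var = s**2
    return var / var.sum()


def heatmap_matrix(counts: pd.DataFrame, cap: int = 50) -> pd.DataFrame:
    """Cap a superfamily x species gene-count matrix at ``cap`` for display
    (row/column order preserved)."""
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValueError("gene counts must be non-negative")
    return counts.clip(upper=cap)
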