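"""Differential gene scoring (normZ) and ROC evaluation of re-annotations.

The scorer follows the normZ procedure used for pooled-screen analysis:
read columns are normalised to a common total, log2 fold changes of
treatment over control are scaled by an empirical-Bayes standard deviation
estimated from guides of similar control abundance, guide z-scores are
summed per gene and divided by sqrt(n).  One-sided normal p-values and
Benjamini-Hochberg FDRs are reported separately for the hypersensitising
(negative) and resisting (positive) directions.

Fold changes are deliberately not re-centred: scaling every column to a
common total deflates neutral guides in treatments whose strong responders
absorb read share, which biases neutral guides mildly toward the
hypersensitising side.  This compositional artefact is a documented
property of the normZ family of scorers and is preserved here so that
gene-level calls behave like the field's reference tool; removing it would
also erase the absolute effect scale that the directional FDR calls rest
on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import NON_TARGETING


@dataclass
class ScreenDesign:
    """Which count columns are control vs treatment, and scorer knobs.

    Treatment column i is paired with control column i modulo the number of
    controls.  ``norm_total`` is the common read total each column is scaled
    to before the pseudocount; ``half_window`` is half the size of the
    control-abundance window used for variance smoothing.
    """

    control_cols: Sequence[str]
    treatment_cols: Sequence[str]
    pseudocount: float = 5.0
    norm_total: float = 1.0e7
    half_window: int = 500

    def __post_init__(self) -> None:
        if not self.control_cols or not self.treatment_cols:
            raise ValueError("need at least one control and one treatment column")


def bh_fdr(p: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(list(p), dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to bh_fdr")
    return multipletests(p, method="fdr_bh")[1]


def _guide_z(
    counts: pd.DataFrame, ctrl: str, treat: str, design: ScreenDesign
) -> np.ndarray:
    nc = design.norm_total * counts[ctrl].to_numpy(float) / counts[ctrl].sum()
    nt = design.norm_total * counts[treat].to_numpy(float) / counts[treat].sum()
    fc = np.log2((nt + design.pseudocount) / (nc + design.pseudocount))
    if np.std(fc) == 0:
        raise ValueError("zero-variance fold-change distribution")
    order = np.argsort(-nc, kind="stable")  # most abundant in control first
    fc_sorted = fc[order]
    w = 2 * design.half_window
    sigma = (
        pd.Series(fc_sorted)
        .rolling(window=w, min_periods=2, center=True)
        .std()
        .bfill()
        .ffill()
        .to_numpy()
    )
    # empirical-Bayes monotonicity: variance never shrinks as abundance drops
    sigma = np.maximum.accumulate(sigma)
    sigma[sigma == 0] = np.nan
    z_sorted = fc_sorted / sigma
    z = np.empty_like(z_sorted)
    z[order] = z_sorted
    return np.nan_to_num(z)


def normz_scores(
    counts: pd.DataFrame,
    guide_to_gene: Mapping[str, object],
    design: ScreenDesign,
) -> pd.DataFrame:
    """Gene-level normZ scores with directional p-values and FDRs.

    ``guide_to_gene`` maps guide ids to a symbol or an iterable of symbols;
    a guide mapping to several genes contributes its z-score to each of
    them.  Guides mapped to nothing or to the non-targeting label are used
    for normalisation and variance estimation but excluded from gene
    aggregation.
    """
    pairs = [
        (design.control_cols[i % len(design.control_cols)], t)
        for i, t in enumerate(design.treatment_cols)
    ]
    z_cols = [ _guide_z(counts, c, t, design) for c, t in pairs ]

    # expand the (possibly multi-valued) guide -> gene mapping once
    guide_idx: list[int] = []
    gene_of: list[str] = []
    pos = {g: i for i, g in enumerate(counts.index)}
    for gid, target in guide_to_gene.items():
        if gid not in pos or target is None:
            continue
        symbols = [target] if isinstance(target, str) else list(target)
        for sym in symbols:
            if sym and sym != NON_TARGETING:
                guide_idx.append(pos[gid])
                gene_of.append(sym)
    if not gene_of:
        raise ValueError("no guide maps to any gene")
    gene_of = np.asarray(gene_of)
    guide_idx = np.asarray(guide_idx)

    z_stack = np.concatenate([z[guide_idx] for z in z_cols])
    gene_stack = np.tile(gene_of, len(z_cols))
    grouped = pd.Series(z_stack).groupby(gene_stack)
    sumz = grouped.sum()
    n_obs = grouped.count()
    normz = sumz / np.sqrt(n_obs)
    p_hyper = sps.norm.cdf(normz)
    p_resist = sps.norm.sf(normz)
    out = pd.DataFrame(
        {
            "n_guides": (n_obs // len(z_cols)).astype(int),
            "sumZ": sumz,
            "normZ": normz,
            "p_hypersensitising": p_hyper,
            "p_resisting": p_resist,
            "fdr_hypersensitising": bh_fdr(p_hyper),
            "fdr_resisting": bh_fdr(p_resist),
        }
    )
    out.index.name = "gene"
    return out.sort_values("normZ")


# ---------------------------------------------------------------------------
# ROC evaluation


@dataclass
class ROCResult:
    curve: list[tuple[float, float]]
    auc: float
    precision: float
    recall: float
    n_actual_positives: int
    n_positives: int
    n_true_positives: int
    fdr_cutoff: float


def _directional_positives(result: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Genes significant in their normZ-sign direction at the FDR cutoff."""
    hyper = result["normZ"] < 0
    fdr = np.where(hyper, result["fdr_hypersensitising"], result["fdr_resisting"])
    df = pd.DataFrame(
        {
            "direction": np.where(hyper, "hypersensitising", "resisting"),
            "fdr": fdr,
            "abs_normz": result["normZ"].abs(),
        },
        index=result.index,
    )
    return df[df["fdr"] <= cutoff]


def roc_analysis(
    truth: pd.DataFrame, candidate: pd.DataFrame, fdr_cutoff: float = 0.5
) -> ROCResult:
    """How well a re-annotation scheme recovers the ground-truth discoveries.

    Actual positives are genes the ground-truth scoring calls at
    ``fdr_cutoff`` or better in either direction; candidate positives are
    the candidate's calls at the same cutoff, taken in order of ascending
    FDR (ties by descending |normZ|, then symbol).  A candidate positive is
    a true positive only when it is an actual positive in the same
    direction.  The curve walks the ranked calls with axes normalised
    within the called set (x = cumulative FP / total FP, y = cumulative
    TP / total TP), is anchored at (0,0) and (1,1), and is integrated by
    the trapezoid rule — so the AUC measures whether false calls are
    concentrated late in the ranking, independent of how many actual
    positives the scheme recovers (that is what recall reports).
    """
    actual = _directional_positives(truth, fdr_cutoff)
    if actual.empty:
        raise ValueError("zero actual positives; recall undefined")
    actual_dir = actual["direction"].to_dict()
    positives = _directional_positives(candidate, fdr_cutoff)
    positives = positives.assign(_sym=positives.index).sort_values(
        by=["fdr", "abs_normz", "_sym"], ascending=[True, False, True]
    )

    n_actual = len(actual)
    hits = [
        actual_dir.get(gene) == row["direction"] for gene, row in positives.iterrows()
    ]
    tp_total = int(sum(hits))
    fp_total = len(hits) - tp_total
    tp = fp = 0
    curve: list[tuple[float, float]] = [(0.0, 0.0)]
    for hit in hits:
        tp += hit
        fp += not hit
        curve.append(
            (fp / fp_total if fp_total else 0.0, tp / tp_total if tp_total else 0.0)
        )
    if curve[-1] != (1.0, 1.0):
        curve.append((1.0, 1.0))
    xs, ys = zip(*curve)
    auc = float(np.trapezoid(ys, xs))
    n_pos = len(positives)
    precision = tp_total / n_pos if n_pos else float("nan")
    recall = tp_total / n_actual
    return ROCResult(curve, auc, precision, recall, n_actual, n_pos, tp_total, fdr_cutoff)


def bundle_stratify(
    truth: pd.DataFrame,
    candidate: pd.DataFrame,
    guides_per_gene: Mapping[str, int],
) -> pd.DataFrame:
    """Through-origin slope of candidate vs truth normZ per guides-per-gene stratum.

    Mis-annotation schemes dilute or concentrate per-gene guide support;
    genes sharing a guide count fall on a common line through the origin in
    the candidate-vs-truth normZ plane, and the slope measures retained
    discovery strength.  Strata with fewer than 3 genes get slope NaN.
    """
    shared = truth.index.intersection(candidate.index)
    rows = []
    strata = pd.Series({g: guides_per_gene.get(g) for g in shared}).dropna()
    for n, genes in strata.groupby(strata).groups.items():
        x = truth.loc[genes, "normZ"].to_numpy()
        y = candidate.loc[genes, "normZ"].to_numpy()
        denom = float(np.sum(x * x))
        slope = float(np.sum(x * y) / denom) if len(genes) >= 3 and denom > 0 else float("nan")
        rows.append({"guides_per_gene": int(n), "n_genes": len(genes), "slope": slope})
    return pd.DataFrame(rows).sort_values("guides_per_gene").reset_index(drop=True)
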