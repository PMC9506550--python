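"""Per-feature two-way block ANOVA, fold changes, DAM selection and PCA.

The model for each feature's log2 intensities is the additive linear
model

    y = mu + block + organ + line + organ:line + error

fitted on the (near-)balanced 48-sample design with sequential (Type I)
sums of squares in the order block, organ, line, interaction, each term
F-tested against the residual mean square.  With two blocks and a
balanced design the fixed-block decomposition is identical to treating
the experiment as a random block, and Type I and Type III sums of
squares coincide.

A differentially accumulating metabolite (DAM) is a feature with
p(line) or p(organ x line) below ``p_max`` and |log2 fold change|
(Bd3-1 over Bd21, per organ) above ``min_abs_log2_fc``; the defaults
are p < 0.01 and |log2 FC| > 1 (FC > 2).  Fold change is the
difference of per-line log2 means, i.e. the log2 geometric-mean ratio.
No multiple-testing correction is applied by default (an optional
Benjamini-Hochberg switch is exposed).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .featuretable import FeatureTable, LINES, ORGANS

__all__ = [
    "AnovaResult", "DamCall", "EffectPartition",
    "anova_all", "anova_two_way_block", "fold_change_per_organ",
    "select_dams", "effect_partition", "pca_scores",
]

TERMS = ("block", "organ", "line", "interaction")


@dataclass(frozen=True)
class AnovaResult:
    feature_id: str
    F_organ: float
    F_line: float
    F_interaction: float
    p_organ: float
    p_line: float
    p_interaction: float
    df: dict


@dataclass(frozen=True)
class DamCall:
    feature_id: str
    organ: str
    log2_fc: float
    p_line: float
    p_interaction: float
    passes: bool
    p_max: float
    min_abs_log2_fc: float


@dataclass(frozen=True)
class EffectPartition:
    """Membership of features in the O / L / OxL significance sets."""

    members: dict     # set name -> frozenset of feature ids
    venn: dict        # region label ('O', 'O&L', 'O&L&OxL', ...) -> count

    @property
    def n_any(self) -> int:
        return len(frozenset().union(*self.members.values()))


def _design_projectors(design: pd.DataFrame):
    """Orthonormal bases for the sequential model terms.

    Returns (Q, slices) where Q is the orthonormal basis of the full
    design matrix built term by term (intercept, block, organ, line,
    organ:line) and ``slices`` maps each term to its column range, so
    that the Type I sum of squares of a term is ||Q_term' y||^2.
    """
    n = len(design)
    cols = [np.ones((n, 1))]
    counts = {}
    exps = sorted(design["experiment"].unique())
    organs = [o for o in ORGANS if o in set(design["organ"])]
    lines = [l for l in LINES if l in set(design["line"])]
    if len(lines) != 2:
        raise ValueError("both lines must be present in the design")
    counts["block"] = len(exps) - 1
    for e in exps[1:]:
        cols.append((design["experiment"] == e).to_numpy(float)[:, None])
    counts["organ"] = len(organs) - 1
    for o in organs[1:]:
        cols.append((design["organ"] == o).to_numpy(float)[:, None])
    counts["line"] = 1
    lvec = (design["line"] == lines[1]).to_numpy(float)[:, None]
    cols.append(lvec)
    counts["interaction"] = len(organs) - 1
    for o in organs[1:]:
        cols.append(lvec * (design["organ"] == o).to_numpy(float)[:, None])
    X = np.hstack(cols)
    Q, R = np.linalg.qr(X)
    if np.min(np.abs(np.diag(R))) < 1e-8 * np.max(np.abs(np.diag(R))):
        raise ValueError("design matrix is rank deficient; check the sample design")
    slices, start = {}, 1
    for term in TERMS:
        slices[term] = slice(start, start + counts[term])
        start += counts[term]
    return Q, slices


def _check_cells(table: FeatureTable) -> None:
    cells = table.design.groupby(["organ", "line"]).size()
    thin = cells[cells < 2]
    if len(thin):
        raise ValueError(f"organ x line cells with < 2 observations: {list(thin.index)}")


def anova_all(table: FeatureTable) -> pd.DataFrame:
    """Vectorized two-way block ANOVA over every feature.

    Returns a DataFrame indexed by feature_id with F and p columns for
    organ, line and interaction (block is a nuisance term).
    """
    if table.transformed != "log2":
        raise ValueError("ANOVA expects a preprocessed (log2) table")
    _check_cells(table)
    Y = table.intensities.to_numpy()          # features x samples
    Q, slices = _design_projectors(table.design)
    n = Y.shape[1]
    proj = Y @ Q                              # features x basis columns
    ss = {t: (proj[:, slices[t]] ** 2).sum(axis=1) for t in TERMS}
    total_ss = (Y ** 2).sum(axis=1) - n * Y.mean(axis=1) ** 2
    model_ss = sum(ss.values())
    resid_ss = np.maximum(total_ss - model_ss, 0.0)
    df = {t: slices[t].stop - slices[t].start for t in TERMS}
    df_resid = n - 1 - sum(df.values())
    ms_resid = resid_ss / df_resid
    out = {"feature_id": table.features["feature_id"].to_numpy()}
    for t in ("organ", "line", "interaction"):
        ms = ss[t] / df[t]
        with np.errstate(divide="ignore", invalid="ignore"):
            F = np.where(ms_resid > 0, ms / ms_resid,
                         np.where(ms > 1e-12, np.inf, 0.0))
        p = stats.f.sf(F, df[t], df_resid)
        out[f"F_{t}"] = F
        out[f"p_{t}"] = p
    res = pd.DataFrame(out).set_index("feature_id")
    res.attrs["df"] = {**df, "residual": df_resid}
    return res


def anova_two_way_block(table: FeatureTable, feature_id: str) -> AnovaResult:
    """Single-feature convenience wrapper around :func:`anova_all`."""
    res = anova_all(table)
    if feature_id not in res.index:
        raise KeyError(feature_id)
    r = res.loc[feature_id]
    return AnovaResult(feature_id, r.F_organ, r.F_line, r.F_interaction,
                       r.p_organ, r.p_line, r.p_interaction, res.attrs["df"])


def fold_change_per_organ(table: FeatureTable,
                          feature_id: str | None = None):
    """log2 fold change Bd3-1 over Bd21 per organ.

    With ``feature_id`` given, returns a dict organ -> log2 FC; otherwise
    a DataFrame (features x organs).
    """
    if table.transformed != "log2":
        raise ValueError("fold change expects a preprocessed (log2) table")
    fc = {}
    for organ in ORGANS:
        hi = table.samples_where(organ=organ, line=LINES[1])
        lo = table.samples_where(organ=organ, line=LINES[0])
        if not hi or not lo:
            raise ValueError(f"organ {organ!r} absent from the design")
        fc[organ] = (table.intensities[hi].mean(axis=1)
                     - table.intensities[lo].mean(axis=1))
    fc = pd.DataFrame(fc)
    if feature_id is not None:
        if feature_id not in fc.index:
            raise KeyError(feature_id)
        return fc.loc[feature_id].to_dict()
    return fc


def select_dams(anova: pd.DataFrame, fcs: pd.DataFrame,
                p_max: float = 0.01, min_abs_log2_fc: float = 1.0,
                bh: bool = False) -> pd.DataFrame:
    """Apply the DAM rule per feature per organ.

    A feature passes in an organ when (p_line <= p_max or
    p_interaction <= p_max) and |log2 FC| > min_abs_log2_fc.  With
    ``bh=True`` the line/interaction p-values are Benjamini-Hochberg
    adjusted across features first.
    """
    if p_max <= 0 or min_abs_log2_fc <= 0:
        raise ValueError("thresholds must be positive")
    from .pathenrich import bh_fdr
    p_line = anova["p_line"].to_numpy()
    p_int = anova["p_interaction"].to_numpy()
    if bh:
        p_line = np.asarray(bh_fdr(p_line))
        p_int = np.asarray(bh_fdr(p_int))
    rows = []
    for j, organ in enumerate(ORGANS):
        lfc = fcs[organ].reindex(anova.index).to_numpy()
        passes = ((p_line <= p_max) | (p_int <= p_max)) & (np.abs(lfc) > min_abs_log2_fc)
        rows.append(pd.DataFrame({
            "feature_id": anova.index, "organ": organ, "log2_fc": lfc,
            "p_line": p_line, "p_interaction": p_int, "passes": passes,
            "p_max": p_max, "min_abs_log2_fc": min_abs_log2_fc,
        }))
    return pd.concat(rows, ignore_index=True)


def effect_partition(anova: pd.DataFrame, p_max: float = 0.01) -> EffectPartition:
    """Venn partition of the O / L / OxL significance sets."""
    if not 0 < p_max < 1:
        raise ValueError("p_max must be in (0, 1)")
    sets = {
        "O": frozenset(anova.index[anova["p_organ"] <= p_max]),
        "L": frozenset(anova.index[anova["p_line"] <= p_max]),
        "OxL": frozenset(anova.index[anova["p_interaction"] <= p_max]),
    }
    names = list(sets)
    venn = {}
    for r in (1, 2, 3):
        for combo in combinations(names, r):
            inside = frozenset.intersection(*(sets[c] for c in combo))
            outside = frozenset().union(*(sets[c] for c in names if c not in combo)) \
                if len(combo) < 3 else frozenset()
            venn["&".join(combo)] = len(inside - outside)
    return EffectPartition(sets, venn)


def pca_scores(table: FeatureTable, n_components: int = 3):
    """PCA of samples over mean-centered feature variables.

    Returns ``(scores, explained)`` where ``scores`` is a samples x
    components DataFrame and ``explained`` the fraction of variance per
    component (non-increasing).
    """
    if n_components > table.n_samples:
        raise ValueError("fewer samples than requested components")
    X = table.intensities.to_numpy().T        # samples x features
    X = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    var = s ** 2
    explained = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    scores = U[:, :n_components] * s[:n_components]
    cols = [f"PC{i+1}" for i in range(n_components)]
    return (pd.DataFrame(scores, index=table.design["sample_id"], columns=cols),
            explained[:n_components])
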