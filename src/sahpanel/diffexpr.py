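"""Moderated differential-expression testing.

The testing engine is an empirical-Bayes moderated two-sample t: gene-wise
residual variances are shrunk toward a common prior variance ``s0_sq``
with prior degrees of freedom ``d0``, both estimated from the observed
variance distribution by matching moments of ``log(s^2)`` (digamma /
trigamma inversion). The moderated statistic is referred to a t
distribution with ``d + d0`` degrees of freedom. With ``d0 = 0`` it
reduces to the ordinary pooled t; as ``d0 -> inf`` it tends to a z score
standardized by ``s0``.

Count matrices are brought onto the log scale with a log2-CPM transform
before testing, so one engine serves both dialects.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datasets import ExpressionDataset

VOLCANO_CAP = 320.0  # ordinate used when p_adj underflows to 0


@dataclasses.dataclass(frozen=True)
class Contrast:
    """A named two-group comparison: ``group_a`` (test) vs ``group_b`` (reference)."""

    name: str
    group_a: str
    group_b: str

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError("contrast groups must differ")

    @classmethod
    def between(cls, group_a: str, group_b: str) -> "Contrast":
        return cls(f"{group_a}_vs_{group_b}", group_a, group_b)


@dataclasses.dataclass
class ModerationState:
    """Empirical-Bayes variance-shrinkage parameters.

    ``d0`` may be ``inf`` (complete shrinkage); the moderated variance is
    ``(d0*s0_sq + d*s_sq) / (d0 + d)`` for finite ``d0`` and ``s0_sq``
    otherwise.
    """

    d0: float
    s0_sq: float
    s_sq: np.ndarray
    d: float

    def moderated_variance(self) -> np.ndarray:
        if np.isinf(self.d0):
            return np.full_like(self.s_sq, self.s0_sq)
        if self.d0 == 0:
            return self.s_sq.copy()
        return (self.d0 * self.s0_sq + self.d * self.s_sq) / (self.d0 + self.d)


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve polygamma(1, x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_moderation(s_sq: np.ndarray, d: float) -> ModerationState:
    """Fit the prior (d0, s0_sq) by moments of log(s^2).

    If ``e = log(s^2) - digamma(d/2) + log(d/2)`` then across genes
    ``E[e] = log(s0^2) + digamma(d0/2) - log(d0/2)`` and
    ``Var[e] = trigamma(d/2) + trigamma(d0/2)``; the excess variance of
    ``e`` over ``trigamma(d/2)`` identifies ``d0``. Nonpositive excess
    means the gene variances are no more spread than sampling alone
    explains, and ``d0`` is taken as infinite.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    positive = s_sq[s_sq > 0]
    if positive.size < 2:
        return ModerationState(d0=np.inf, s0_sq=float(np.mean(s_sq) if s_sq.size else 1.0), s_sq=s_sq, d=d)
    z = np.log(positive)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    n = e.size
    excess = np.var(e, ddof=0) * n / (n - 1) - float(special.polygamma(1, d / 2.0))
    if excess <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(np.mean(e)))
    else:
        half_d0 = _trigamma_inverse(excess)
        d0 = 2.0 * half_d0
        # E[log s^2] = log s0^2 + digamma(d/2)-log(d/2) - digamma(d0/2)+log(d0/2)
        s0_sq = float(np.exp(np.mean(e) + special.digamma(half_d0) - np.log(half_d0)))
    return ModerationState(d0=d0, s0_sq=s0_sq, s_sq=s_sq, d=d)


def transform_counts(dataset: ExpressionDataset, pseudocount: float = 0.5) -> ExpressionDataset:
    """log2(CPM + pseudocount) with per-sample library-size normalization."""
    if dataset.dialect != "counts":
        raise ValueError("transform_counts expects a counts-dialect dataset")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    totals = dataset.values.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    cpm = dataset.values / totals * 1e6
    logged = np.log2(cpm + pseudocount)
    return ExpressionDataset(logged, dataset.metadata.copy(), dialect="log")


def moderated_t_test(
    dataset: ExpressionDataset,
    contrast: Contrast,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-gene moderated t test for one contrast.

    Parameters
    ----------
    prior_df : float, optional
        Override the estimated prior degrees of freedom; ``0`` gives the
        ordinary pooled t, ``inf`` full shrinkage to the prior variance.

    Returns a DataFrame indexed by gene id with columns ``log2_fc``,
    ``t_stat``, ``p_raw``, ``p_adj`` (Benjamini-Hochberg), ``regulation``
    and ``passes_filter`` (the last two filled by
    :func:`select_de_genes`; initialized to "none"/False here).
    """
    if dataset.dialect != "log":
        raise ValueError("moderated_t_test expects log-dialect data; use transform_counts first")
    ids_a = dataset.samples_in_group(contrast.group_a)
    ids_b = dataset.samples_in_group(contrast.group_b)
    na, nb = len(ids_a), len(ids_b)
    if na < 2 or nb < 2:
        raise ValueError(
            f"contrast {contrast.name}: need >=2 samples per group (got {na} vs {nb})"
        )

    a = dataset.values[ids_a].to_numpy(dtype=float)
    b = dataset.values[ids_b].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2_fc = mean_a - mean_b
    d = na + nb - 2
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + ((b - mean_b[:, None]) ** 2).sum(axis=1)
    s_sq = ss / d

    if prior_df is None:
        state = estimate_moderation(s_sq, d)
    else:
        base = estimate_moderation(s_sq, d)
        s0 = base.s0_sq if np.isfinite(base.s0_sq) and base.s0_sq > 0 else float(np.mean(s_sq[s_sq > 0]) or 1.0)
        state = ModerationState(d0=float(prior_df), s0_sq=s0, s_sq=s_sq, d=d)

    var_mod = state.moderated_variance()
    se = np.sqrt(var_mod * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2_fc / se, np.sign(log2_fc) * np.inf)
    t = np.where((se == 0) & (log2_fc == 0), 0.0, t)  # flat gene: t=0, p=1
    df_total = state.d + (state.d0 if np.isfinite(state.d0) else 0.0)
    if np.isinf(state.d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.clip(p, 0.0, 1.0)
    p_adj = benjamini_hochberg(p)

    out = pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "t_stat": t,
            "p_raw": p,
            "p_adj": p_adj,
            "regulation": "none",
            "passes_filter": False,
        },
        index=dataset.gene_ids,
    )
    out.attrs["moderation"] = state
    out.attrs["contrast"] = contrast.name
    return out


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up FDR adjustment (monotone, clipped to [0, 1])."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def select_de_genes(
    results: pd.DataFrame,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    use_adjusted: bool = False,
) -> tuple[pd.DataFrame, int, int]:
    """Apply the fold-change + p-value filter and call regulation.

    ``fc_threshold`` is on the linear scale: 1.5 means |log2 FC| >= log2 1.5.
    Returns (annotated results sorted by gene id within the selection,
    up count, down count).
    """
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1 (linear scale)")
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must lie in (0, 1)")
    out = results.copy()
    pcol = "p_adj" if use_adjusted else "p_raw"
    passes = (np.abs(out["log2_fc"]) >= np.log2(fc_threshold)) & (out[pcol] < p_threshold)
    out["passes_filter"] = passes
    out["regulation"] = np.where(
        passes & (out["log2_fc"] > 0), "up", np.where(passes & (out["log2_fc"] < 0), "down", "none")
    )
    selected = out[out["passes_filter"]].sort_index()
    up = int((selected["regulation"] == "up").sum())
    down = int((selected["regulation"] == "down").sum())
    return out, up, down


def de_summary(n_selected: int, n_total: int, up: int, down: int) -> dict:
    """Headline numbers of a DE run: counts and the percent of the universe."""
    return {
        "n_selected": n_selected,
        "n_total": n_total,
        "percent_of_genes": 100.0 * n_selected / n_total,
        "up": up,
        "down": down,
    }


def rle_statistics(dataset: ExpressionDataset) -> pd.DataFrame:
    """Relative log expression QC: per-sample median and IQR of deviations.

    RLE(g, j) = value(g, j) - median over samples of value(g, .). On a
    well-normalized dataset every per-sample median sits near zero. A
    single-sample dataset yields all-zero RLE (flagged, not an error).
    """
    if dataset.dialect != "log":
        raise ValueError("rle_statistics expects log-dialect data")
    values = dataset.values.to_numpy(dtype=float)
    med = np.median(values, axis=1, keepdims=True)
    rle = values - med
    q1, q2, q3 = np.percentile(rle, [25, 50, 75], axis=0)
    out = pd.DataFrame(
        {"median": q2, "q1": q1, "q3": q3, "iqr": q3 - q1},
        index=dataset.sample_ids,
    )
    out.attrs["degenerate_single_sample"] = dataset.n_samples == 1
    return out


def volcano_table(results: pd.DataFrame, cap: float = VOLCANO_CAP) -> pd.DataFrame:
    """Plot-ready table: log2 FC against -log10 of the adjusted p.

    Zero adjusted p-values are capped at ``cap`` so the ordinate stays
    finite. ``regulation`` doubles as the colour key (up / down / none).
    """
    with np.errstate(divide="ignore"):
        ordinate = -np.log10(results["p_adj"].to_numpy(dtype=float))
    ordinate = np.where(np.isfinite(ordinate), np.minimum(ordinate, cap), cap)
    return pd.DataFrame(
        {
            "gene_id": results.index,
            "log2_fc": results["log2_fc"].to_numpy(),
            "neg_log10_fdr": ordinate,
            "regulation": results["regulation"].to_numpy(),
        }
    )
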