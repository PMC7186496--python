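"""Fisher's exact (hypergeometric) pathway enrichment.

Notation, per pathway: ``N`` genes measured (the universe), ``n`` of them
in the pathway, ``N_f`` differential genes, ``n_f`` differential genes in
the pathway. The hypergeometric probability of an overlap of exactly
``x`` is ``C(n, x) C(N-n, N_f-x) / C(N, N_f)``.

Two tail conventions are provided:

``upper_tail`` (default)
    ``p = sum_{x >= n_f} pmf(x)`` — the standard one-sided enrichment
    test.
``as_printed``
    ``p = min(1, 2 * sum_{x=1}^{n_f} pmf(x))`` — a doubled lower-partial
    sum found in some published formulations; it is not a proper tail
    probability (the cap at 1 is required) and is kept only for
    faithfulness to that convention.

The universe is all measured genes — it is *not* restricted to the union
of pathway annotations.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .diffexpr import benjamini_hochberg

MODES = ("upper_tail", "as_printed")


@dataclasses.dataclass
class EnrichmentRow:
    pathway_id: str
    N: int
    n: int
    N_f: int
    n_f: int
    p_F: float
    mode: str = "upper_tail"

    def __post_init__(self) -> None:
        if not (0 <= self.n_f <= min(self.n, self.N_f) and self.n <= self.N and self.N_f <= self.N):
            raise ValueError(f"inconsistent enrichment counts for {self.pathway_id}")


def _check_domain(N: int, n: int, N_f: int) -> None:
    if N < 0 or n < 0 or N_f < 0 or N < max(n, N_f):
        raise ValueError(f"invalid hypergeometric parameters N={N}, n={n}, N_f={N_f}")


def _log_comb(a: np.ndarray | int, b: np.ndarray | int) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_pmf(x: int, N: int, n: int, N_f: int) -> float:
    """P(overlap = x) computed in log space; 0 outside the support."""
    _check_domain(N, n, N_f)
    lo = max(0, N_f - (N - n))
    hi = min(n, N_f)
    if x < lo or x > hi:
        return 0.0
    log_p = _log_comb(n, x) + _log_comb(N - n, N_f - x) - _log_comb(N, N_f)
    return float(np.exp(log_p))


def _pmf_support(N: int, n: int, N_f: int) -> tuple[np.ndarray, np.ndarray]:
    lo = max(0, N_f - (N - n))
    hi = min(n, N_f)
    xs = np.arange(lo, hi + 1)
    log_p = _log_comb(n, xs) + _log_comb(N - n, N_f - xs) - _log_comb(N, N_f)
    return xs, np.exp(log_p)


def fisher_pathway_test(N: int, n: int, N_f: int, n_f: int, mode: str = "upper_tail") -> float:
    """Enrichment p-value for an overlap of ``n_f`` under the chosen tail."""
    _check_domain(N, n, N_f)
    if n_f < 0 or n_f > min(n, N_f):
        raise ValueError(f"n_f={n_f} outside [0, min(n, N_f)]")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    xs, pmf = _pmf_support(N, n, N_f)
    if mode == "upper_tail":
        return float(min(1.0, pmf[xs >= n_f].sum()))
    return float(min(1.0, 2.0 * pmf[(xs >= 1) & (xs <= n_f)].sum()))


def enrich_all(
    de_genes: Iterable[str],
    universe: Iterable[str],
    pathways: Mapping[str, set[str] | Iterable[str]],
    p_report: float = 0.001,
    mode: str = "upper_tail",
) -> pd.DataFrame:
    """Test every pathway for enrichment of ``de_genes`` within ``universe``.

    Pathway membership is intersected with the universe first; a pathway
    with no measured member gets ``n = 0`` and ``p_F = 1`` (upper-tail
    convention). Rows are sorted by ascending ``p_F`` with pathway-id
    tie-break; ``significant`` flags ``p_F < p_report`` and a BH column is
    included for reference (the report filter uses raw ``p_F``).
    """
    universe = set(universe)
    de = set(de_genes)
    if not de <= universe:
        raise ValueError("de_genes must be a subset of the universe")
    if not pathways:
        raise ValueError("empty pathway collection")
    N, N_f = len(universe), len(de)
    rows = []
    for pid in pathways:
        members = set(pathways[pid]) & universe
        n = len(members)
        n_f = len(members & de)
        p = fisher_pathway_test(N, n, N_f, n_f, mode=mode) if n else 1.0
        rows.append(
            {"pathway_id": pid, "N": N, "n": n, "N_f": N_f, "n_f": n_f, "p_F": p}
        )
    table = pd.DataFrame(rows)
    table["p_BH"] = benjamini_hochberg(table["p_F"].to_numpy())
    table["significant"] = table["p_F"] < p_report
    table = table.sort_values(["p_F", "pathway_id"], kind="mergesort").reset_index(drop=True)
    table.attrs["mode"] = mode
    table.attrs["p_report"] = p_report
    return table
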