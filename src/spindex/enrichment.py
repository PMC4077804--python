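"""Over-representation analysis (ORA) of a focus gene list against gene sets.

For each set the overlap k between the focus list (size n) and the set's
members within the reference universe (size K of N) is scored by the
hypergeometric upper tail P(X >= k) — the one-sided Fisher exact test —
and Benjamini-Hochberg adjusted across all tested sets.  The universe is
the detectable-gene background (all genes passing the reliability
threshold), not the whole annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["GeneSetCollection", "read_gmt", "write_gmt", "select_focus", "ora"]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets plus the reference universe they are tested against."""

    sets: dict[str, tuple[str, frozenset[str]]]  # set_id -> (name, members)
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("reference universe is empty")


def read_gmt(path, universe) -> GeneSetCollection:
    """Read a GMT file: ``set_id <TAB> description <TAB> gene1 <TAB> ...``."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs id, description and >= 1 gene")
            set_id, desc, genes = parts[0], parts[1], parts[2:]
            members = frozenset(g for g in genes if g)
            if set_id in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            sets[set_id] = (desc, members)
    return GeneSetCollection(sets=sets, universe=frozenset(universe))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_id, (desc, members) in collection.sets.items():
            fh.write("\t".join([set_id, desc, *sorted(members)]) + "\n")


def select_focus(
    de_records: pd.DataFrame,
    universe,
    p_cut: float = 0.05,
    fc_cut: float = 1.5,
) -> list[str]:
    """Focus genes: p < p_cut and two-sided fold change beyond fc_cut,
    restricted to the universe.  Genes passing the filters but absent from
    the universe are dropped with a warning."""
    from .diffexpr import call_de

    calls = call_de(de_records, p_cut=p_cut, fc_cut=fc_cut)
    universe = frozenset(universe)
    if not universe:
        raise ValueError("reference universe is empty")
    selected = list(calls.fc_filtered)
    outside = [g for g in selected if g not in universe]
    if outside:
        warnings.warn(
            f"{len(outside)} focus gene(s) absent from the universe were dropped",
            stacklevel=2,
        )
    return [g for g in selected if g in universe]


def ora(
    focus,
    collection: GeneSetCollection,
    alpha: float = 0.05,
    alternative: str = "greater",
    adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """Hypergeometric over-representation test for every gene set.

    Returns one row per tested set with k, K, n, N, p, p_adj and the
    ``enriched`` call (p_adj < alpha).  Sets with no universe overlap are
    skipped with a warning.  ``alternative='two-sided'`` switches to the
    two-sided Fisher exact test.
    """
    focus = frozenset(focus)
    stray = focus - collection.universe
    if stray:
        raise ValueError(f"focus genes outside the universe: {sorted(stray)[:5]}")
    n = len(focus)
    big_n = len(collection.universe)
    rows = []
    for set_id, (name, members) in collection.sets.items():
        in_universe = members & collection.universe
        big_k = len(in_universe)
        if big_k == 0:
            warnings.warn(f"gene set {set_id!r} has no universe overlap; skipped", stacklevel=2)
            continue
        k = len(focus & in_universe)
        if alternative == "greater":
            p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        elif alternative == "two-sided":
            table = [
                [k, n - k],
                [big_k - k, big_n - big_k - (n - k)],
            ]
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        rows.append((set_id, name, k, big_k, n, big_n, min(p, 1.0)))
    out = pd.DataFrame(
        rows, columns=["set_id", "name", "k", "K", "n", "N", "p"]
    ).set_index("set_id")
    if len(out):
        out["p_adj"] = multipletests(out["p"], method=adjust)[1]
        out["enriched"] = out["p_adj"] < alpha
        out = out.sort_values("p")
    else:
        out["p_adj"] = []
        out["enriched"] = []
    return out
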