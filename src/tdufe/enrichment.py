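"""Local over-representation analysis of a selected gene list against GMT gene sets.

For each gene set the overlap with the selected list is scored by the exact
one-sided hypergeometric tail (Fisher exact upper tail): with universe size
``Nu``, ``n`` set members inside the universe, ``s`` selected genes and ``k``
of them in the set,

    p = P[X >= k],  X ~ Hypergeometric(Nu, n, s).

P-values are BH-adjusted across all tested sets. The universe defaults to
whatever feature list the caller passes — typically all features that survived
tensor filtering, not the whole genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .gene_selection import bh_adjust

__all__ = ["GeneSetCollection", "read_gmt", "hypergeometric_enrichment"]


@dataclass
class GeneSetCollection:
    """Named gene sets (symbol lists); empty sets are dropped at load time."""

    sets: dict[str, list[str]]
    source: str | None = None

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path, uppercase: bool = True) -> GeneSetCollection:
    """Parse a GMT file: tab-separated ``name<TAB>description<TAB>member...``.

    Duplicate members within a set are removed (first occurrence kept);
    symbols are upper-cased by default (human gene convention). Lines with
    fewer than three fields are an error reported with the line number; an
    empty file yields an empty collection.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path.name}:{lineno}: malformed GMT line (needs name, "
                    f"description and at least one member, got {len(fields)} fields)"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            members: list[str] = []
            seen = set()
            for m in fields[2:]:
                m = m.strip()
                if not m:
                    continue
                if uppercase:
                    m = m.upper()
                if m not in seen:
                    seen.add(m)
                    members.append(m)
            if members:
                sets[name] = members
    return GeneSetCollection(sets=sets, source=str(path))


def _normalize(genes: Iterable[str], uppercase: bool) -> list[str]:
    seen = set()
    out = []
    for g in genes:
        g = g.strip()
        if uppercase:
            g = g.upper()
        if g and g not in seen:
            seen.add(g)
            out.append(g)
    return out


def hypergeometric_enrichment(
    selected: Sequence[str],
    universe: Sequence[str],
    sets: GeneSetCollection,
    min_overlap: int = 1,
    uppercase: bool = True,
    strict: bool = True,
) -> pd.DataFrame:
    """Test each gene set for over-representation in the selected list.

    Set members are first intersected with the universe; sets whose overlap
    with the selected list falls below ``min_overlap`` are not tested. Rows
    are sorted by adjusted p ascending, then term name, so output is
    independent of input ordering. The ``overlap`` column formats as
    ``"k/n"`` with ``n`` the set size within the universe.

    With ``strict=True`` selected genes outside the universe are an error
    (they would silently deflate every p-value); otherwise they are dropped.
    """
    universe_list = _normalize(universe, uppercase)
    if not universe_list:
        raise ValueError("empty universe")
    universe_set = set(universe_list)
    selected_list = _normalize(selected, uppercase)
    offenders = [g for g in selected_list if g not in universe_set]
    if offenders:
        if strict:
            raise ValueError(
                f"{len(offenders)} selected genes not in universe, e.g. {offenders[:5]}"
            )
        selected_list = [g for g in selected_list if g in universe_set]
    selected_set = set(selected_list)

    nu, s = len(universe_set), len(selected_set)
    rows = []
    for term in sorted(sets.sets):
        members = set(sets.sets[term]) & universe_set
        n = len(members)
        overlap = sorted(members & selected_set)
        k = len(overlap)
        if k < min_overlap:
            continue
        p = float(hypergeom.sf(k - 1, nu, n, s))
        rows.append(
            {
                "term": term,
                "overlap": f"{k}/{n}",
                "overlap_count": k,
                "set_size": n,
                "universe_size": nu,
                "selected_size": s,
                "p_raw": min(p, 1.0),
                "overlapping_genes": ",".join(overlap),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "term",
            "overlap",
            "overlap_count",
            "set_size",
            "universe_size",
            "selected_size",
            "p_raw",
            "overlapping_genes",
        ],
    )
    if len(df):
        df["p_adjusted"] = bh_adjust(df["p_raw"].to_numpy())
        df = df.sort_values(["p_adjusted", "term"], kind="mergesort").reset_index(drop=True)
    else:
        df["p_adjusted"] = pd.Series(dtype=float)
    return df
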