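"""Evidence integration: intersection of gene sets from multiple sources.

Combines a literature-derived gene list with per-dataset significant gene
sets and reports Venn-style overlap counts.  Protein complexes carried by a
GeneSet are excluded — only gene symbols are intersected.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .formats_io import GeneSet


@dataclass(frozen=True)
class OverlapReport:
    """Overlap structure across evidence sources.

    ``region_counts`` maps each non-empty subset of source names (as a
    sorted tuple) to the number of genes found in exactly those sources.
    ``core_set`` holds the genes present in at least ``min_sources``
    sources.
    """

    source_sizes: dict[str, int]
    region_counts: dict[tuple[str, ...], int]
    core_set: GeneSet
    min_sources: int

    def pairwise(self, a: str, b: str) -> int:
        """Size of the full pairwise intersection |A ∩ B| (not region count)."""
        return sum(
            n for names, n in self.region_counts.items() if a in names and b in names
        )

    @property
    def union_size(self) -> int:
        return sum(self.region_counts.values())

    def to_tsv(self) -> str:
        lines = ["# region\tcount"]
        for names in sorted(self.region_counts, key=lambda t: (len(t), t)):
            lines.append("&".join(names) + f"\t{self.region_counts[names]}")
        lines.append(f"# core (>= {self.min_sources} sources)\t{len(self.core_set)}")
        return "\n".join(lines) + "\n"


def venn_counts(sources: list[GeneSet]) -> dict[tuple[str, ...], int]:
    """Exact-region counts for 2 or 3 gene sets.

    Returns the 2^s - 1 region sizes keyed by sorted source-name tuples;
    counts sum to the size of the union.
    """
    if not 2 <= len(sources) <= 3:
        raise ValueError("venn_counts supports 2 or 3 sources")
    names = [s.name for s in sources]
    if len(set(names)) != len(names):
        raise ValueError("source names must be distinct")
    sets = {s.name: set(s.symbols) for s in sources}
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(sources) + 1):
        for combo in combinations(sorted(names), r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(
                *(sets[n] for n in names if n not in combo), set()
            ) if len(combo) < len(names) else set()
            counts[combo] = len(inside - outside)
    return counts


def intersect_sources(
    sources: list[GeneSet], min_sources: int | None = None
) -> OverlapReport:
    """Genes present in at least ``min_sources`` evidence sources.

    The default (``min_sources = None``) requires presence in every source,
    reproducing the all-sources intersection.  Region counts are reported
    for up to 3 sources; with more sources only the core set and sizes are
    populated.
    """
    if len(sources) < 2:
        raise ValueError("need at least 2 sources to intersect")
    k = len(sources) if min_sources is None else min_sources
    if not 1 <= k <= len(sources):
        raise ValueError(
            f"min_sources must lie in [1, {len(sources)}], got {min_sources}"
        )
    names = [s.name for s in sources]
    if len(set(names)) != len(names):
        raise ValueError("source names must be distinct")

    membership: dict[str, set[str]] = {}
    for s in sources:
        for gene in s.symbols:
            membership.setdefault(gene, set()).add(s.name)

    core = frozenset(g for g, srcs in membership.items() if len(srcs) >= k)
    region_counts = venn_counts(sources) if len(sources) <= 3 else {}
    return OverlapReport(
        source_sizes={s.name: len(s.symbols) for s in sources},
        region_counts=region_counts,
        core_set=GeneSet(name="core", symbols=core),
        min_sources=k,
    )
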