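"""Worm-mammal ortholog groups and cross-species PUF target overlap.

Orthology is treated as transitive: worm genes sharing any mammalian
ortholog collapse into one unit, and likewise mammalian genes sharing a
worm ortholog — i.e. ortholog groups are the connected components of the
bipartite orthology graph. Before grouping, promiscuous genes are capped:
worm genes with more than ten mammalian partners are removed, then
mammalian genes with more than ten worm partners. A group counts as shared
between FBF and a mammalian PUF if any worm member is an FBF target and any
mammal member a PUF target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd


@dataclass
class OrthologMap:
    """Bipartite worm-mammal orthology edges."""

    edges: list[tuple[str, str]]
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        self.edges = sorted(set(self.edges))
        worms = {w for w, _ in self.edges}
        mams = {m for _, m in self.edges}
        clash = worms & mams
        if clash:
            raise ValueError(
                f"gene ids appear on both sides (not bipartite): {sorted(clash)[:5]}"
            )

    @property
    def worm_genes(self) -> set[str]:
        return {w for w, _ in self.edges}

    @property
    def mammal_genes(self) -> set[str]:
        return {m for _, m in self.edges}

    @classmethod
    def from_tsv(cls, path: str | Path, provenance: str | None = None) -> "OrthologMap":
        df = pd.read_csv(path, sep="\t")
        if not {"worm_gene", "mammal_gene"} <= set(df.columns):
            raise ValueError("ortholog TSV needs worm_gene and mammal_gene columns")
        return cls(
            edges=list(zip(df["worm_gene"].astype(str), df["mammal_gene"].astype(str))),
            provenance=provenance or str(path),
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.edges, columns=["worm_gene", "mammal_gene"]).to_csv(
            path, sep="\t", index=False
        )


def filter_degree(
    omap: OrthologMap, max_orthologs: int = 10, iterate: bool = False
) -> OrthologMap:
    """Drop promiscuous genes: worm pass first, then mammal pass.

    A worm gene with more than ``max_orthologs`` mammalian partners is
    removed with all its edges; then mammalian genes with more than
    ``max_orthologs`` worm partners likewise (degrees re-evaluated after the
    worm pass). With ``iterate`` the two passes repeat until stable.
    """
    edges = list(omap.edges)
    while True:
        worm_deg: dict[str, int] = {}
        for w, _ in edges:
            worm_deg[w] = worm_deg.get(w, 0) + 1
        edges = [(w, m) for w, m in edges if worm_deg[w] <= max_orthologs]
        mam_deg: dict[str, int] = {}
        for _, m in edges:
            mam_deg[m] = mam_deg.get(m, 0) + 1
        new_edges = [(w, m) for w, m in edges if mam_deg[m] <= max_orthologs]
        changed = len(new_edges) != len(edges)
        edges = new_edges
        if not iterate or not changed:
            break
    return OrthologMap(edges=edges, provenance=omap.provenance)


@dataclass(frozen=True)
class OrthologGroup:
    group_id: str
    worm_members: frozenset[str]
    mammal_members: frozenset[str]


def build_groups(omap: OrthologMap) -> list[OrthologGroup]:
    """Connected components of the bipartite graph, as ortholog groups.

    Component search realizes the transitive-orthology rule on both sides
    at once. Groups are ordered (and numbered) by their smallest worm
    member for determinism.
    """
    g = nx.Graph()
    for w, m in omap.edges:
        g.add_edge(("w", w), ("m", m))
    comps = []
    for comp in nx.connected_components(g):
        worm = frozenset(n for side, n in comp if side == "w")
        mam = frozenset(n for side, n in comp if side == "m")
        comps.append((min(worm), worm, mam))
    comps.sort(key=lambda t: t[0])
    return [
        OrthologGroup(group_id=f"OG{i:05d}", worm_members=w, mammal_members=m)
        for i, (_, w, m) in enumerate(comps)
    ]


@dataclass
class OverlapReport:
    shared_fraction: float  # NaN when no worm-targeted group exists
    n_worm_targeted: int
    n_shared: int
    unmatched_worm_targets: list[str] = field(default_factory=list)
    unmatched_mammal_targets: list[str] = field(default_factory=list)
    table: pd.DataFrame | None = None

    def to_json_dict(self) -> dict:
        frac = self.shared_fraction
        return {
            "shared_fraction": None if pd.isna(frac) else frac,
            "n_worm_targeted": self.n_worm_targeted,
            "n_shared": self.n_shared,
            "n_unmatched_worm_targets": len(self.unmatched_worm_targets),
            "n_unmatched_mammal_targets": len(self.unmatched_mammal_targets),
        }


def compute_overlap(
    groups: Sequence[OrthologGroup],
    worm_targets: Iterable[str],
    mammal_targets: Iterable[str],
) -> OverlapReport:
    """Fraction of worm-targeted ortholog groups shared with the mammal PUF.

    A group is worm-targeted if any worm member is a worm target, shared if
    additionally any mammal member is a mammal target. Target genes absent
    from every group are reported as unmatched, not silently dropped. The
    baseline "all ortholog groups" fraction is this same computation with
    the full worm gene universe as ``worm_targets``.
    """
    worm_targets = set(worm_targets)
    mammal_targets = set(mammal_targets)
    rows = []
    n_targeted = n_shared = 0
    for g in groups:
        targeted = bool(g.worm_members & worm_targets)
        shared = targeted and bool(g.mammal_members & mammal_targets)
        n_targeted += targeted
        n_shared += shared
        rows.append({
            "group_id": g.group_id,
            "worm_members": ",".join(sorted(g.worm_members)),
            "mammal_members": ",".join(sorted(g.mammal_members)),
            "worm_targeted": targeted,
            "shared": shared,
        })
    all_worm = set().union(*(g.worm_members for g in groups)) if groups else set()
    all_mam = set().union(*(g.mammal_members for g in groups)) if groups else set()
    return OverlapReport(
        shared_fraction=(n_shared / n_targeted) if n_targeted else float("nan"),
        n_worm_targeted=n_targeted,
        n_shared=n_shared,
        unmatched_worm_targets=sorted(worm_targets - all_worm),
        unmatched_mammal_targets=sorted(mammal_targets - all_mam),
        table=pd.DataFrame(rows),
    )


def groups_to_tsv(groups: Sequence[OrthologGroup], path: str | Path) -> None:
    pd.DataFrame([{
        "group_id": g.group_id,
        "worm_members": ",".join(sorted(g.worm_members)),
        "mammal_members": ",".join(sorted(g.mammal_members)),
    } for g in groups]).to_csv(path, sep="\t", index=False)
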