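"""Normalized abundance profiles, rollups, krona/chord exports, clustering.

Spectral counts are normalized to the total spectral count of each
measurement (column fractions).  Metaprotein matrices roll up to taxonomic
families (via the LCA ancestor at family rank, with an explicit unassigned
bucket) or to biological processes (a metaprotein's counts are duplicated
into each of its Biological Process keywords).  Sample similarity uses the
cityblock distance with unweighted average linkage (UPGMA); the linkage is
implemented here because its merge order is fixed by a deterministic
lexicographic tie-break among equal-distance candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from scipy import stats

from .metaproteins import Metaprotein
from .taxonomy import UNASSIGNED, TaxonomyTree, ancestor_at_rank, lineage

UNASSIGNED_LABEL = "unassigned"
OTHER_FUNCTIONS = "Other_Functions"
ALPHA = 0.05


@dataclass
class AbundanceMatrix:
    """Entities x samples matrix of spectral counts or fractions."""

    data: pd.DataFrame  # rows: entity ids, columns: sample ids
    mode: str = "raw-counts"  # or "fractions"

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def column_ids(self) -> list[str]:
        return list(self.data.columns)


def matrix_from_metaproteins(metaproteins: Sequence[Metaprotein]) -> AbundanceMatrix:
    samples = sorted({s for mp in metaproteins for s in mp.spectral_counts})
    rows = {
        mp.group_id: [mp.spectral_counts.get(s, 0) for s in samples]
        for mp in metaproteins
    }
    data = pd.DataFrame.from_dict(rows, orient="index", columns=samples, dtype=float)
    return AbundanceMatrix(data=data.sort_index(), mode="raw-counts")


def normalize(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Divide each column by its total; all-zero columns stay zero (warning)."""
    if matrix.mode == "fractions":
        return matrix
    if (matrix.data.values < 0).any():
        raise ValueError("negative counts in abundance matrix")
    totals = matrix.data.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"all-zero column(s): {list(totals.index[zero])}")
    safe = totals.replace(0, 1.0)
    return AbundanceMatrix(data=matrix.data / safe, mode="fractions")


def rollup(
    metaproteins: Sequence[Metaprotein],
    tree: TaxonomyTree,
    level: str,
) -> AbundanceMatrix:
    """Aggregate metaprotein counts to ``"family"`` or ``"biological-process"``.

    The family rollup conserves spectra (unassigned bucket included); the
    process rollup duplicates counts into each keyword, so its totals can
    exceed the metaprotein totals.
    """
    samples = sorted({s for mp in metaproteins for s in mp.spectral_counts})
    acc: dict[str, np.ndarray] = {}

    def add(label: str, mp: Metaprotein) -> None:
        row = acc.setdefault(label, np.zeros(len(samples)))
        for i, s in enumerate(samples):
            row[i] += mp.spectral_counts.get(s, 0)

    for mp in metaproteins:
        if level == "family":
            fam = (
                ancestor_at_rank(tree, mp.lca_tax_id, "family")
                if mp.lca_tax_id is not None
                else UNASSIGNED
            )
            label = UNASSIGNED_LABEL if fam is UNASSIGNED else tree.nodes[fam].name
            add(label, mp)
        elif level == "biological-process":
            processes = sorted(mp.biological_processes) or [UNASSIGNED_LABEL]
            for proc in processes:
                add(proc, mp)
        else:
            raise ValueError(f"unknown rollup level {level!r}")
    data = pd.DataFrame.from_dict(acc, orient="index", columns=samples)
    return AbundanceMatrix(data=data.sort_index(), mode="raw-counts")


def krona_rows(
    metaproteins: Sequence[Metaprotein],
    tree: TaxonomyTree,
    ranks: Sequence[str] = ("superkingdom", "phylum", "class", "order", "family"),
) -> list[tuple[int, list[str]]]:
    """One (total spectra, rank-wise lineage) row per metaprotein."""
    rows = []
    for mp in metaproteins:
        names = lineage(tree, mp.lca_tax_id, ranks) if mp.lca_tax_id else []
        names = [UNASSIGNED_LABEL if n is UNASSIGNED else n for n in names] or [
            UNASSIGNED_LABEL
        ] * len(ranks)
        rows.append((mp.total_spectra, names))
    return rows


def write_krona(rows: Iterable[tuple[int, list[str]]], sink: IO[str]) -> None:
    """Krona-compatible text: count, then one lineage name per column."""
    for count, names in rows:
        sink.write("\t".join([str(count), *names]) + "\n")


@dataclass
class ChordMatrix:
    families: list[str]
    processes: list[str]  # last entry may be the Other_Functions bucket
    cells: pd.DataFrame  # families x processes, spectra shared


def _top_k(totals: Mapping[str, float], k: int) -> list[str]:
    # ties broken lexicographically, descending abundance
    return [
        label
        for label, _ in sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    ]


def chord_matrix(
    family_matrix: AbundanceMatrix,
    process_matrix: AbundanceMatrix,
    joint_counts: Mapping[tuple[str, str], float],
    k: int = 20,
) -> ChordMatrix:
    """Family x process co-abundance for the top-k of each axis.

    Processes outside the top k are summed into an ``Other_Functions``
    bucket, so process-level totals are conserved for the retained families.
    """
    fam_totals = family_matrix.data.sum(axis=1).to_dict()
    proc_totals = process_matrix.data.sum(axis=1).to_dict()
    families = _top_k(fam_totals, k)
    processes = _top_k(proc_totals, k)
    need_bucket = len(proc_totals) > len(processes)
    columns = processes + ([OTHER_FUNCTIONS] if need_bucket else [])
    cells = pd.DataFrame(0.0, index=families, columns=columns)
    for (family, process), count in joint_counts.items():
        if family not in cells.index:
            continue
        column = process if process in processes else OTHER_FUNCTIONS
        if column in cells.columns:
            cells.loc[family, column] += count
    return ChordMatrix(families=families, processes=columns, cells=cells)


def joint_family_process_counts(
    metaproteins: Sequence[Metaprotein], tree: TaxonomyTree
) -> dict[tuple[str, str], float]:
    """Total spectra shared by each (family, biological process) pair."""
    joint: dict[tuple[str, str], float] = {}
    for mp in metaproteins:
        fam = (
            ancestor_at_rank(tree, mp.lca_tax_id, "family")
            if mp.lca_tax_id is not None
            else UNASSIGNED
        )
        fam_label = UNASSIGNED_LABEL if fam is UNASSIGNED else tree.nodes[fam].name
        for proc in sorted(mp.biological_processes) or [UNASSIGNED_LABEL]:
            key = (fam_label, proc)
            joint[key] = joint.get(key, 0.0) + mp.total_spectra
    return joint


# ---------------------------------------------------------------------------
# UPGMA clustering with deterministic tie-break


@dataclass
class _ClusterNode:
    members: tuple[str, ...]  # sorted leaf labels
    height: float = 0.0
    children: tuple["_ClusterNode", ...] = ()


@dataclass
class Dendrogram:
    """Binary merge tree over samples; heights are merge distances."""

    root: _ClusterNode
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = field(
        default_factory=list
    )

    @property
    def leaves(self) -> tuple[str, ...]:
        return self.root.members

    def to_newick(self) -> str:
        """Ultrametric Newick; node depth = merge distance / 2."""

        def walk(node: _ClusterNode, parent_height: float) -> str:
            length = (parent_height - node.height) / 2.0
            if not node.children:
                return f"{node.members[0]}:{length:g}"
            inner = ",".join(walk(c, node.height) for c in node.children)
            return f"({inner}):{length:g}"

        if not self.root.children:
            return f"{self.root.members[0]};"
        inner = ",".join(walk(c, self.root.height) for c in self.root.children)
        return f"({inner}):0;"


def cluster_samples(matrix: AbundanceMatrix) -> Dendrogram:
    """UPGMA over samples with cityblock distances on the fraction profiles.

    Among equal-distance merge candidates the pair with the lexicographically
    smallest member labels merges first, making the tree reproducible.
    """
    samples = list(matrix.column_ids)
    if len(samples) < 2:
        raise ValueError("clustering needs at least 2 samples")
    profiles = matrix.data.values.T  # samples x entities
    dist = squareform(pdist(profiles, metric="cityblock"))

    clusters: dict[int, _ClusterNode] = {
        i: _ClusterNode(members=(s,)) for i, s in enumerate(samples)
    }
    sizes = {i: 1 for i in clusters}
    d = {
        (i, j): dist[i, j]
        for i in range(len(samples))
        for j in range(i + 1, len(samples))
    }
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []
    next_id = len(samples)
    while len(clusters) > 1:
        (i, j), dij = min(
            d.items(),
            key=lambda kv: (
                kv[1],
                tuple(sorted(clusters[kv[0][0]].members + clusters[kv[0][1]].members)),
            ),
        )
        a, b = clusters.pop(i), clusters.pop(j)
        merged = _ClusterNode(
            members=tuple(sorted(a.members + b.members)),
            height=dij,
            children=(a, b) if a.members <= b.members else (b, a),
        )
        merges.append((a.members, b.members, dij))
        # UPGMA: distance to the union is the size-weighted mean
        for k in clusters:
            dik = d.pop((min(i, k), max(i, k)))
            djk = d.pop((min(j, k), max(j, k)))
            d[(min(next_id, k), max(next_id, k))] = (
                sizes[i] * dik + sizes[j] * djk
            ) / (sizes[i] + sizes[j])
        for key in [key for key in d if i in key or j in key]:
            del d[key]
        sizes[next_id] = sizes.pop(i) + sizes.pop(j)
        clusters[next_id] = merged
        next_id += 1
    return Dendrogram(root=next(iter(clusters.values())), merges=merges)


def compare_groups(
    group_a: Sequence[float], group_b: Sequence[float], alpha: float = ALPHA
) -> tuple[float, float, bool]:
    """Two-sided two-sample Student's t-test (pooled variance).

    Returns (t statistic, p-value, significant flag with p < alpha).  Two
    zero-variance groups with equal means give p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, False
        t = np.inf if a.mean() > b.mean() else -np.inf
        return t, 0.0, True
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p), bool(p < alpha)
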