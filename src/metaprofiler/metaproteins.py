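"""Metaprotein aggregation: UniRef50 grouping, spectral counting, LCA taxonomy.

Redundant homologous proteins are grouped into metaproteins by their UniRef50
cluster; proteins without a cluster fall back to per-accession singleton
groups so nothing is silently discarded.  A spectrum contributes one count to
each distinct group reachable through its accessions, never more than once to
the same group.  Each group's taxonomy is the lowest common ancestor of its
members' taxa, and function annotations (UniProtKB keywords, EC, KO) are
unioned across members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

from .psm_io import SearchResultSet
from .taxonomy import TaxonomyTree, lca

SINGLETON_PREFIX = "SINGLETON:"

#: Keyword category holding UniProtKB biological-process annotations.
BIOLOGICAL_PROCESS = "Biological process"

_ANNOTATION_COLUMNS = (
    "accession",
    "uniref50_id",
    "tax_id",
    "keywords",
    "ec",
    "ko",
    "description",
)


class AnnotationFormatError(Exception):
    pass


@dataclass(frozen=True)
class ProteinAnnotation:
    accession: str
    uniref50_id: str | None = None
    tax_id: int | None = None
    keywords: frozenset[tuple[str, str]] = frozenset()  # (category, keyword)
    ec_numbers: frozenset[str] = frozenset()
    ko_ids: frozenset[str] = frozenset()
    description: str = ""


@dataclass
class Metaprotein:
    group_id: str
    member_accessions: set[str] = field(default_factory=set)
    peptides: set[str] = field(default_factory=set)
    spectral_counts: dict[str, int] = field(default_factory=dict)
    lca_tax_id: int | None = None
    biological_processes: set[str] = field(default_factory=set)
    keywords: set[tuple[str, str]] = field(default_factory=set)
    ec_numbers: set[str] = field(default_factory=set)
    ko_ids: set[str] = field(default_factory=set)
    description: str = ""

    @property
    def total_spectra(self) -> int:
        return sum(self.spectral_counts.values())


def read_annotation_table(source: IO[str]) -> dict[str, ProteinAnnotation]:
    """Parse the annotation TSV: accession, uniref50_id, tax_id, keywords
    ("Category:Keyword" semicolon-joined), ec, ko, description."""
    header = source.readline().rstrip("\n").split("\t")
    missing = [c for c in _ANNOTATION_COLUMNS if c not in header]
    if missing:
        raise AnnotationFormatError(f"missing column(s) {missing}")
    idx = {c: header.index(c) for c in _ANNOTATION_COLUMNS}
    table: dict[str, ProteinAnnotation] = {}
    for lineno, line in enumerate(source, start=2):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < len(header):
            raise AnnotationFormatError(f"line {lineno}: too few fields")
        accession = fields[idx["accession"]]
        if accession in table:
            raise AnnotationFormatError(f"line {lineno}: duplicate accession {accession}")
        keywords = set()
        for item in fields[idx["keywords"]].split(";"):
            item = item.strip()
            if not item:
                continue
            category, _, keyword = item.partition(":")
            keywords.add((category.strip(), keyword.strip()) if keyword else ("", category.strip()))
        tax_field = fields[idx["tax_id"]].strip()
        table[accession] = ProteinAnnotation(
            accession=accession,
            uniref50_id=fields[idx["uniref50_id"]].strip() or None,
            tax_id=int(tax_field) if tax_field else None,
            keywords=frozenset(keywords),
            ec_numbers=frozenset(x for x in fields[idx["ec"]].split(";") if x.strip()),
            ko_ids=frozenset(x for x in fields[idx["ko"]].split(";") if x.strip()),
            description=fields[idx["description"]].strip(),
        )
    return table


def write_annotation_table(
    annotations: Mapping[str, ProteinAnnotation], sink: IO[str]
) -> None:
    sink.write("\t".join(_ANNOTATION_COLUMNS) + "\n")
    for acc in sorted(annotations):
        a = annotations[acc]
        sink.write(
            "\t".join(
                (
                    a.accession,
                    a.uniref50_id or "",
                    "" if a.tax_id is None else str(a.tax_id),
                    ";".join(
                        sorted(f"{c}:{k}" if c else k for c, k in a.keywords)
                    ),
                    ";".join(sorted(a.ec_numbers)),
                    ";".join(sorted(a.ko_ids)),
                    a.description,
                )
            )
            + "\n"
        )


def _group_id_for(accession: str, annotations: Mapping[str, ProteinAnnotation]) -> str:
    ann = annotations.get(accession)
    if ann is not None and ann.uniref50_id:
        return ann.uniref50_id
    return SINGLETON_PREFIX + accession


def group_by_uniref(
    results: SearchResultSet, annotations: Mapping[str, ProteinAnnotation]
) -> list[Metaprotein]:
    """Group FDR-filtered, merged identifications into metaproteins.

    Every accession maps to exactly one group: its UniRef50 cluster id, else
    a ``SINGLETON:<accession>`` group.  Counting is spectrum-deduplicated per
    group per sample.  Records whose accessions are all unannotated are kept
    as singletons with a warning counter.
    """
    groups: dict[str, Metaprotein] = {}
    counted: set[tuple[str, str]] = set()  # (group_id, spectrum_key)
    n_unannotated = 0
    for record in results.records:
        if all(acc not in annotations for acc in record.accessions):
            n_unannotated += 1
        for accession in record.accessions:
            gid = _group_id_for(accession, annotations)
            mp = groups.setdefault(gid, Metaprotein(group_id=gid))
            mp.member_accessions.add(accession)
            mp.peptides.add(record.peptide)
            if (gid, record.spectrum_key) not in counted:
                counted.add((gid, record.spectrum_key))
                mp.spectral_counts[record.sample_id] = (
                    mp.spectral_counts.get(record.sample_id, 0) + 1
                )
    if n_unannotated:
        warnings.warn(
            f"{n_unannotated} record(s) had no annotated accession; "
            "kept as singleton groups"
        )
    return [groups[gid] for gid in sorted(groups)]


def assign_lca(
    metaprotein: Metaprotein,
    annotations: Mapping[str, ProteinAnnotation],
    tree: TaxonomyTree,
) -> Metaprotein:
    """Set the metaprotein's LCA over the distinct taxa of annotated members.

    Members without a tax_id, or with one absent from the tree, are ignored
    (with a warning for the latter); a group with no usable taxa sits at the
    root.
    """
    tax_ids = set()
    for accession in metaprotein.member_accessions:
        ann = annotations.get(accession)
        if ann is None or ann.tax_id is None:
            continue
        if ann.tax_id not in tree:
            warnings.warn(
                f"tax_id {ann.tax_id} of {accession} absent from tree; ignored"
            )
            continue
        tax_ids.add(ann.tax_id)
    metaprotein.lca_tax_id = lca(tree, tax_ids) if tax_ids else tree.root_id
    return metaprotein


def summarize_function(
    metaprotein: Metaprotein, annotations: Mapping[str, ProteinAnnotation]
) -> Metaprotein:
    """Union keyword/EC/KO sets over members; representative description is
    the lexicographically smallest member description (deterministic)."""
    descriptions = []
    for accession in sorted(metaprotein.member_accessions):
        ann = annotations.get(accession)
        if ann is None:
            continue
        metaprotein.keywords |= ann.keywords
        metaprotein.ec_numbers |= ann.ec_numbers
        metaprotein.ko_ids |= ann.ko_ids
        if ann.description:
            descriptions.append(ann.description)
    metaprotein.biological_processes = {
        keyword
        for category, keyword in metaprotein.keywords
        if category == BIOLOGICAL_PROCESS
    }
    metaprotein.description = min(descriptions) if descriptions else ""
    return metaprotein


def build_metaproteins(
    results: SearchResultSet,
    annotations: Mapping[str, ProteinAnnotation],
    tree: TaxonomyTree,
) -> list[Metaprotein]:
    """Full aggregation: group, then annotate taxonomy and function."""
    metaproteins = group_by_uniref(results, annotations)
    for mp in metaproteins:
        assign_lca(mp, annotations, tree)
        summarize_function(mp, annotations)
    return metaproteins


def write_metaprotein_csv(
    metaproteins: Iterable[Metaprotein], tree: TaxonomyTree, sink: IO[str]
) -> None:
    """Export the metaprotein profile as CSV, one row per group."""
    metaproteins = list(metaproteins)
    samples = sorted({s for mp in metaproteins for s in mp.spectral_counts})
    sink.write(
        ",".join(
            ["group_id", "description", "lca_tax_id", "lca_name", "n_members"]
            + samples
        )
        + "\n"
    )
    for mp in metaproteins:
        name = tree.nodes[mp.lca_tax_id].name if mp.lca_tax_id in tree.nodes else ""
        desc = mp.description.replace(",", ";")
        row = [mp.group_id, desc, str(mp.lca_tax_id), name, str(len(mp.member_accessions))]
        row += [str(mp.spectral_counts.get(s, 0)) for s in samples]
        sink.write(",".join(row) + "\n")
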