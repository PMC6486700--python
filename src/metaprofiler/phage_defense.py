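"""Phage, CRISPR and antimicrobial quantification, and the phage-per-cell
geometric estimator.

Viral metaproteins are recognised either by taxonomy (LCA under the Viruses
superkingdom) or — because many phage proteins resolve only to the taxonomy
root — by description terms indicating typical viral functions (capsid, tail,
terminase, ...).  Cellular metaproteins whose description still says
"phage"/"prophage" are counted as prophage proteins of their host lineage.
Phages are assigned to host families by an override table or a genus-token
heuristic; most remain unassigned, which is an expected outcome, not an
error.

The phage-per-cell estimator assumes spherical particles with equal protein
density: a viral-to-host spectral ratio r and diameters d_cell, d_phage give
r * (d_cell / d_phage)^3 phages per cell.  With the defaults (1.0 um cell,
100 nm phage) a community-wide viral protein fraction of 0.4% corresponds to
roughly 4 phages per cell, and per-family ratios of 2.3-2.8% to 20-30.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .metaproteins import Metaprotein
from .taxonomy import UNASSIGNED, TaxonomyTree, ancestor_at_rank

#: Description terms indicating typical viral functions.  "polymerase" is
#: deliberately absent: at root level it would sweep in cellular polymerases.
DEFAULT_VIRAL_TERMS = (
    "phage",
    "prophage",
    "capsid",
    "tail",
    "baseplate",
    "portal",
    "terminase",
    "virion",
    "tape measure",
    "holin",
)

CAS_PROTEIN_PATTERN = re.compile(
    r"\b(cas(?:[1-9]|1[0-3])[a-z]?|csn\d*|cmr\d*)\b", re.IGNORECASE
)
CRISPR_KEYWORDS = ("Antiviral defense",)

ANTIMICROBIAL_TERMS = ("linocin", "lysozyme", "maritimacin", "bacteriocin")

VIRAL_TAXONOMIC = "viral_taxonomic"
VIRAL_BY_FUNCTION = "viral_by_function"
PROPHAGE = "prophage"
NOT_VIRAL = "not_viral"

VIRUSES_NAME = "Viruses"


@dataclass(frozen=True)
class ViralVocabulary:
    terms: tuple[str, ...] = DEFAULT_VIRAL_TERMS

    def __post_init__(self):
        if not self.terms:
            raise ValueError("vocabulary must be non-empty")
        object.__setattr__(self, "terms", tuple(t.lower() for t in self.terms))

    def matches(self, text: str) -> bool:
        low = text.lower()
        return any(
            re.search(rf"\b{re.escape(term)}\b", low) for term in self.terms
        )


@dataclass(frozen=True)
class PhageBurdenParams:
    """Geometric parameters, both in micrometres."""

    cell_diameter_um: float = 1.0
    phage_diameter_um: float = 0.1

    def __post_init__(self):
        if self.cell_diameter_um <= 0 or self.phage_diameter_um <= 0:
            raise ValueError("diameters must be positive")


@dataclass
class PhageHostRecord:
    family: str
    family_spectra: int = 0
    phage_spectra: int = 0
    crispr_spectra: int = 0

    @property
    def phage_fraction(self) -> float | None:
        if self.family_spectra <= 0:
            return None
        return self.phage_spectra / self.family_spectra

    @property
    def crispr_fraction(self) -> float | None:
        if self.family_spectra <= 0:
            return None
        return self.crispr_spectra / self.family_spectra


def _superkingdom_name(tree: TaxonomyTree, tax_id: int) -> str | None:
    sk = ancestor_at_rank(tree, tax_id, "superkingdom")
    return None if sk is UNASSIGNED else tree.nodes[sk].name


_PHAGE_WORD = re.compile(r"\b(pro)?phage\b", re.IGNORECASE)


def classify_viral(
    metaprotein: Metaprotein,
    tree: TaxonomyTree,
    vocabulary: ViralVocabulary = ViralVocabulary(),
) -> str:
    """Classify as viral_taxonomic / viral_by_function / prophage / not_viral.

    Taxonomy wins when the LCA sits under Viruses; root-level groups fall
    back to the description vocabulary; cellular groups whose description
    mentions (pro)phage count as prophage proteins of their host.
    """
    tax_id = metaprotein.lca_tax_id
    if tax_id is None or tax_id == tree.root_id:
        if vocabulary.matches(metaprotein.description):
            return VIRAL_BY_FUNCTION
        return NOT_VIRAL
    if _superkingdom_name(tree, tax_id) == VIRUSES_NAME:
        return VIRAL_TAXONOMIC
    if _PHAGE_WORD.search(metaprotein.description):
        return PROPHAGE
    return NOT_VIRAL


def classify_crispr(metaprotein: Metaprotein) -> bool:
    """True for CRISPR/Cas defense metaproteins (description or keywords)."""
    texts = [metaprotein.description] + [k for _, k in metaprotein.keywords]
    for text in texts:
        if "crispr" in text.lower() or CAS_PROTEIN_PATTERN.search(text):
            return True
    keywords = {k for _, k in metaprotein.keywords}
    return any(kw in keywords for kw in CRISPR_KEYWORDS)


def classify_antimicrobial(metaprotein: Metaprotein) -> bool:
    """True for antimicrobial proteins (keyword, or linocin/lysozyme/...)."""
    if any(k == "Antimicrobial" for _, k in metaprotein.keywords):
        return True
    low = metaprotein.description.lower()
    return any(re.search(rf"\b{term}\b", low) for term in ANTIMICROBIAL_TERMS)


def assign_host(
    metaprotein: Metaprotein,
    tree: TaxonomyTree,
    override_table: Mapping[str, str] | None = None,
    viral_class: str | None = None,
    vocabulary: ViralVocabulary = ViralVocabulary(),
):
    """Host family name for a viral metaprotein, or UNASSIGNED.

    Precedence: override table (keyed by group id, virus LCA name, or
    description) > prophage's own LCA family > genus-token heuristic on the
    virus name ("Bacillus phage SPbeta" -> genus Bacillus -> its family).
    """
    if viral_class is None:
        viral_class = classify_viral(metaprotein, tree, vocabulary)
    overrides = override_table or {}
    lca_name = (
        tree.nodes[metaprotein.lca_tax_id].name
        if metaprotein.lca_tax_id in tree.nodes
        else ""
    )
    for key in (metaprotein.group_id, lca_name, metaprotein.description):
        if key and key in overrides:
            return overrides[key]

    if viral_class == PROPHAGE:
        fam = ancestor_at_rank(tree, metaprotein.lca_tax_id, "family")
        return UNASSIGNED if fam is UNASSIGNED else tree.nodes[fam].name

    genus_to_family = {
        node.name: ancestor_at_rank(tree, node.tax_id, "family")
        for node in tree.nodes.values()
        if node.rank == "genus"
    }
    for name in (lca_name, metaprotein.description):
        token = name.split()[0] if name.split() else ""
        fam = genus_to_family.get(token)
        if fam is not None and fam is not UNASSIGNED:
            return tree.nodes[fam].name
    return UNASSIGNED


@dataclass
class PhageSummary:
    total_spectra: int
    microbial_spectra: int
    phage_spectra: int
    crispr_spectra: int

    @property
    def phage_share_percent(self) -> float:
        return 100.0 * self.phage_spectra / self.total_spectra

    @property
    def crispr_share_percent(self) -> float:
        return 100.0 * self.crispr_spectra / self.total_spectra


def phage_host_table(
    metaproteins: Sequence[Metaprotein],
    tree: TaxonomyTree,
    override_table: Mapping[str, str] | None = None,
    vocabulary: ViralVocabulary = ViralVocabulary(),
) -> tuple[list[PhageHostRecord], PhageSummary]:
    """Per-host-family phage/CRISPR burden table plus the global summary.

    family_spectra come from the microbial family rollup; phage_spectra sum
    the viral metaproteins assigned to that host family (unassigned bucket
    conserves the remainder); fractions are phage- and CRISPR-to-family
    normalized counts.
    """
    records: dict[str, PhageHostRecord] = {}

    def rec(family: str) -> PhageHostRecord:
        return records.setdefault(family, PhageHostRecord(family=family))

    total = phage_total = crispr_total = 0
    for mp in metaproteins:
        spectra = mp.total_spectra
        total += spectra
        viral_class = classify_viral(mp, tree, vocabulary)
        if viral_class in (VIRAL_TAXONOMIC, VIRAL_BY_FUNCTION, PROPHAGE):
            host = assign_host(mp, tree, override_table, viral_class, vocabulary)
            label = "unassigned" if host is UNASSIGNED else host
            rec(label).phage_spectra += spectra
            phage_total += spectra
            continue
        fam = (
            ancestor_at_rank(tree, mp.lca_tax_id, "family")
            if mp.lca_tax_id is not None
            else UNASSIGNED
        )
        label = "unassigned" if fam is UNASSIGNED else tree.nodes[fam].name
        rec(label).family_spectra += spectra
        if classify_crispr(mp):
            rec(label).crispr_spectra += spectra
            crispr_total += spectra
    summary = PhageSummary(
        total_spectra=total,
        microbial_spectra=total - phage_total,
        phage_spectra=phage_total,
        crispr_spectra=crispr_total,
    )
    return [records[f] for f in sorted(records)], summary


def write_phage_host_csv(records: Sequence[PhageHostRecord], sink) -> None:
    sink.write(
        "family,family_spectra,phage_spectra,crispr_spectra,"
        "phage_fraction,crispr_fraction\n"
    )
    for r in records:
        pf = "" if r.phage_fraction is None else f"{r.phage_fraction:.6f}"
        cf = "" if r.crispr_fraction is None else f"{r.crispr_fraction:.6f}"
        sink.write(
            f"{r.family},{r.family_spectra},{r.phage_spectra},"
            f"{r.crispr_spectra},{pf},{cf}\n"
        )


def fraction_to_ratio(fraction: float) -> float:
    """Convert a share of all spectra f to a viral:microbial ratio f/(1-f)."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    return fraction / (1.0 - fraction)


def phages_per_cell(
    viral_to_host_ratio: float, params: PhageBurdenParams = PhageBurdenParams()
) -> float:
    """Phage particles per microbial cell from a spectral abundance ratio.

    Equal protein density and spherical shapes make protein mass scale with
    diameter cubed, so the particle ratio is the spectral ratio times
    (d_cell / d_phage)^3.
    """
    if viral_to_host_ratio < 0:
        raise ValueError("ratio must be >= 0")
    scale = (params.cell_diameter_um / params.phage_diameter_um) ** 3
    return viral_to_host_ratio * scale
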