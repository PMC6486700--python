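"""Synthetic communities with known ground truth for end-to-end testing.

The generator emulates the shape of a multi-plant anaerobic-digester
metaproteomics study: several biogas plants sampled at two time points with
duplicate protein extractions, searched by three engines against a
target-decoy database.  Each community is a weighted mixture of microbial
families carrying function-annotated metaproteins, per-family phage load
(most viral spectra resolving only to the taxonomy root, as observed in real
data), CRISPR and antimicrobial proteins, and a share of metaproteins whose
taxonomy resolves above family rank.  Spectra are drawn multinomially from
Dirichlet-perturbed weights, so family fractions come with the usual
sqrt(p(1-p)/N) sampling error; decoy and entrapment ("false target") PSMs
carry left-shifted scores so the FDR threshold is non-trivial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .metaproteins import ProteinAnnotation
from .psm_io import PsmRecord, SearchResultSet
from .taxonomy import TaxonomyNode, TaxonomyTree

_AMINO = "ACDEFGHIKLMNPQRSTVWY"

ROOT_ID = 1
BACTERIA_ID = 2
ARCHAEA_ID = 2157
VIRUSES_ID = 10239


class CommunityConfigError(Exception):
    pass


@dataclass(frozen=True)
class FamilySpec:
    name: str
    weight: float
    superkingdom: str  # "Bacteria" or "Archaea"
    genus: str
    order: str | None = None


@dataclass(frozen=True)
class MetaproteinSpec:
    uniref_id: str
    weight: float
    processes: tuple[str, ...] = ()
    ec_numbers: tuple[str, ...] = ()
    ko_ids: tuple[str, ...] = ()
    description: str = ""
    tag: str | None = None  # acetoclastic / hydrogenotrophic / acds_bacterial


@dataclass
class CommunitySpec:
    families: list[FamilySpec]
    metaproteins: dict[str, list[MetaproteinSpec]]  # family name -> specs
    phage_load: dict[str, float] = field(default_factory=dict)
    crispr_fraction: float = 0.006
    antimicrobial_fraction: float = 0.003
    unassigned_fraction: float = 0.35
    root_phage_share: float = 0.77  # share of each family's phage weight at root

    def __post_init__(self):
        for fam in self.families:
            if fam.weight <= 0:
                raise CommunityConfigError(f"family {fam.name} weight must be > 0")
        names = {f.name for f in self.families}
        for fam_name in self.phage_load:
            if fam_name not in names:
                raise CommunityConfigError(
                    f"phage_load references unknown family {fam_name!r}"
                )
        for frac in (self.crispr_fraction, self.antimicrobial_fraction,
                     self.unassigned_fraction):
            if not 0 <= frac < 1:
                raise CommunityConfigError("fractions must be in [0, 1)")


@dataclass
class SimulationConfig:
    n_plants: int = 3
    time_points: int = 2
    technical_replicates: int = 2  # duplicate protein extractions
    engines: tuple[str, ...] = ("engineA", "engineB", "engineC")
    spectra_depth: int = 20_000
    # Dirichlet concentrations (None = no perturbation at that level)
    plant_concentration: float | None = 40.0
    time_concentration: float | None = 400.0
    dirichlet_concentration: float | None = 1000.0  # technical replicates
    decoy_fraction: float = 0.3
    false_target_fraction: float = 0.0  # entrapment targets with decoy scores
    engine_detection_prob: float = 0.9
    target_score: tuple[float, float] = (25.0, 5.0)  # mean, sd
    decoy_score: tuple[float, float] = (15.0, 5.0)
    plant_types: tuple[str, ...] = ()  # cycle of methanogenesis types
    seed: int = 0


def default_community() -> CommunitySpec:
    """A biogas-plant-like community: dominant Bacillaceae/Enterobacteriaceae,
    cellulolytic Clostridiaceae, thermophilic clostridia, and methanogens;
    phage loads of 2.3% and 2.8% on the two phage-rich bacterial families."""
    families = [
        FamilySpec("Bacillaceae", 0.20, "Bacteria", "Bacillus", "Bacillales"),
        FamilySpec("Enterobacteriaceae", 0.14, "Bacteria", "Escherichia",
                   "Enterobacterales"),
        FamilySpec("Clostridiaceae", 0.18, "Bacteria", "Clostridium",
                   "Eubacteriales"),
        FamilySpec("Thermoanaerobacteraceae", 0.12, "Bacteria",
                   "Thermoanaerobacter", "Thermoanaerobacterales"),
        FamilySpec("Thermotogaceae", 0.08, "Bacteria", "Thermotoga",
                   "Thermotogales"),
        FamilySpec("Methanosarcinaceae", 0.18, "Archaea", "Methanosarcina",
                   "Methanosarcinales"),
        FamilySpec("Methanocaldococcaceae", 0.10, "Archaea",
                   "Methanocaldococcus", "Methanococcales"),
    ]
    mp = {
        "Bacillaceae": [
            MetaproteinSpec("UniRef50_B0001", 0.30, ("Glycolysis",),
                            ("2.7.1.11",), (), "6-phosphofructokinase"),
            MetaproteinSpec("UniRef50_B0002", 0.25, ("Transport",), (),
                            ("K02027",), "Sugar ABC transporter"),
            MetaproteinSpec("UniRef50_B0003", 0.25, ("Cellulose degradation",),
                            ("3.2.1.4",), (), "Endoglucanase"),
            MetaproteinSpec("UniRef50_B0004", 0.20, ("Sporulation",), (), (),
                            "Stage II sporulation protein D"),
        ],
        "Enterobacteriaceae": [
            MetaproteinSpec("UniRef50_E0001", 0.40, ("Glycolysis",),
                            ("2.7.1.11",), (), "Phosphofructokinase"),
            MetaproteinSpec("UniRef50_E0002", 0.35, ("Fermentation",),
                            ("1.1.1.1",), (), "Alcohol dehydrogenase"),
            MetaproteinSpec("UniRef50_E0003", 0.25, ("Transport",), (),
                            ("K01999",), "Branched-chain amino acid transporter"),
        ],
        "Clostridiaceae": [
            MetaproteinSpec("UniRef50_C0001", 0.40, ("Cellulose degradation",),
                            ("3.2.1.4",), (), "Cellulase"),
            MetaproteinSpec("UniRef50_C0002", 0.30, ("Fermentation",),
                            ("1.1.1.27",), (), "L-lactate dehydrogenase"),
            MetaproteinSpec("UniRef50_C0003", 0.30, ("One-carbon metabolism",),
                            (), ("K00198",), "CO dehydrogenase, bacterial"),
        ],
        "Thermoanaerobacteraceae": [
            MetaproteinSpec("UniRef50_T0001", 0.50, ("Fermentation",),
                            ("2.7.1.11", "1.2.7.1"), (),
                            "Pyruvate:ferredoxin oxidoreductase"),
            MetaproteinSpec("UniRef50_T0002", 0.50, ("One-carbon metabolism",),
                            (), ("K00198", "K00193"), "Acetyl-CoA synthase,"
                            " bacterial", tag="acds_bacterial"),
        ],
        "Thermotogaceae": [
            MetaproteinSpec("UniRef50_G0001", 0.60, ("Glycolysis",),
                            ("2.7.1.11",), (), "Glucokinase"),
            MetaproteinSpec("UniRef50_G0002", 0.40, ("Fermentation",),
                            ("4.3.1.19",), (), "Threonine ammonia-lyase"),
        ],
        "Methanosarcinaceae": [
            MetaproteinSpec("UniRef50_M0001", 0.35, ("Methanogenesis",), (),
                            ("K00399", "K00401"), "Methyl-coenzyme M reductase"
                            " alpha subunit", tag="hydrogenotrophic"),
            MetaproteinSpec("UniRef50_M0002", 0.40, ("Methanogenesis",), (),
                            ("K00193", "K00194", "K00925"),
                            "Acetyl-CoA decarbonylase/synthase complex",
                            tag="acetoclastic"),
            MetaproteinSpec("UniRef50_M0003", 0.25, ("Methanogenesis",), (),
                            ("K04480",), "Methanol-corrinoid methyltransferase",
                            tag="acetoclastic"),
        ],
        "Methanocaldococcaceae": [
            MetaproteinSpec("UniRef50_H0001", 0.55, ("Methanogenesis",), (),
                            ("K00399", "K00402"), "Methyl-coenzyme M reductase",
                            tag="hydrogenotrophic"),
            MetaproteinSpec("UniRef50_H0002", 0.45, ("Methanogenesis",), (),
                            ("K00672", "K01499"), "Formylmethanofuran"
                            " transferase", tag="hydrogenotrophic"),
        ],
    }
    return CommunitySpec(
        families=families,
        metaproteins=mp,
        phage_load={"Clostridiaceae": 0.023, "Enterobacteriaceae": 0.028},
        crispr_fraction=0.006,
        antimicrobial_fraction=0.003,
        unassigned_fraction=0.35,
    )


# ---------------------------------------------------------------------------
# Reference building


@dataclass
class _Entry:
    """One drawable unit of the master mixture."""

    kind: str  # microbial / phage / crispr / antimicrobial
    family: str
    group_id: str
    weight: float
    accessions: tuple[str, ...]
    tag: str | None = None
    at_family: bool = True  # False: taxonomy resolves above family rank


@dataclass
class Reference:
    annotations: dict[str, ProteinAnnotation]
    tree: TaxonomyTree
    entries: list[_Entry]
    family_tax: dict[str, int]


def build_reference(spec: CommunitySpec) -> Reference:
    """Consistent accession/UniRef50/taxonomy/function tables for a community.

    The taxonomy tree holds every family lineage (superkingdom > order >
    family > genus > species) plus a Viruses branch with one named phage per
    loaded family.  A deterministic share of each family's metaproteins (by
    weight, closest to ``unassigned_fraction``) is annotated at order level
    so its LCA resolves above family rank.
    """
    nodes: dict[int, TaxonomyNode] = {
        ROOT_ID: TaxonomyNode(ROOT_ID, ROOT_ID, "no rank", "root"),
        BACTERIA_ID: TaxonomyNode(BACTERIA_ID, ROOT_ID, "superkingdom", "Bacteria"),
        ARCHAEA_ID: TaxonomyNode(ARCHAEA_ID, ROOT_ID, "superkingdom", "Archaea"),
        VIRUSES_ID: TaxonomyNode(VIRUSES_ID, ROOT_ID, "superkingdom", "Viruses"),
    }
    next_id = 1000
    family_tax: dict[str, int] = {}
    genus_tax: dict[str, int] = {}
    species_tax: dict[str, int] = {}
    order_tax: dict[str, int] = {}
    sk_id = {"Bacteria": BACTERIA_ID, "Archaea": ARCHAEA_ID}
    for fam in spec.families:
        if fam.superkingdom not in sk_id:
            raise CommunityConfigError(
                f"unsupported superkingdom {fam.superkingdom!r}"
            )
        order_id = next_id
        nodes[order_id] = TaxonomyNode(
            order_id, sk_id[fam.superkingdom], "order",
            fam.order or f"{fam.name}_order",
        )
        fam_id = order_id + 1
        nodes[fam_id] = TaxonomyNode(fam_id, order_id, "family", fam.name)
        genus_id = order_id + 2
        nodes[genus_id] = TaxonomyNode(genus_id, fam_id, "genus", fam.genus)
        species_id = order_id + 3
        nodes[species_id] = TaxonomyNode(
            species_id, genus_id, "species", f"{fam.genus} speciosus"
        )
        family_tax[fam.name] = fam_id
        genus_tax[fam.name] = genus_id
        species_tax[fam.name] = species_id
        order_tax[fam.name] = order_id
        next_id += 10

    annotations: dict[str, ProteinAnnotation] = {}
    entries: list[_Entry] = []
    fam_weight = {f.name: f.weight for f in spec.families}
    total_w = sum(fam_weight.values())

    def add_annotation(ann: ProteinAnnotation) -> None:
        annotations[ann.accession] = ann

    for fam in spec.families:
        mps = spec.metaproteins.get(fam.name, [])
        if not mps:
            raise CommunityConfigError(f"family {fam.name} has no metaproteins")
        mp_total = sum(m.weight for m in mps)
        # flag metaproteins as order-level until the unassigned weight share
        # is reached (deterministic: spec order)
        unassigned_budget = spec.unassigned_fraction * mp_total
        spent = 0.0
        for k, mp in enumerate(mps):
            at_order = spent + mp.weight <= unassigned_budget + 1e-12
            if at_order:
                spent += mp.weight
            tax_id = order_tax[fam.name] if at_order else species_tax[fam.name]
            accs = tuple(f"{mp.uniref_id}_A{j}" for j in (1, 2))
            for acc in accs:
                add_annotation(
                    ProteinAnnotation(
                        accession=acc,
                        uniref50_id=mp.uniref_id,
                        tax_id=tax_id,
                        keywords=frozenset(
                            ("Biological process", p) for p in mp.processes
                        ),
                        ec_numbers=frozenset(mp.ec_numbers),
                        ko_ids=frozenset(mp.ko_ids),
                        description=mp.description,
                    )
                )
            entries.append(
                _Entry(
                    kind="microbial",
                    family=fam.name,
                    group_id=mp.uniref_id,
                    weight=fam_weight[fam.name] / total_w * mp.weight / mp_total,
                    accessions=accs,
                    tag=mp.tag,
                    at_family=not at_order,
                )
            )
        base = fam_weight[fam.name] / total_w
        # per-family CRISPR and antimicrobial metaproteins
        if spec.crispr_fraction > 0:
            uid = f"UniRef50_CR_{fam.name}"
            acc = f"{uid}_A1"
            add_annotation(
                ProteinAnnotation(
                    accession=acc,
                    uniref50_id=uid,
                    tax_id=species_tax[fam.name],
                    keywords=frozenset({("Biological process",
                                         "Antiviral defense")}),
                    description="CRISPR-associated protein Cas1",
                )
            )
            entries.append(
                _Entry("crispr", fam.name, uid, base * spec.crispr_fraction,
                       (acc,))
            )
        if spec.antimicrobial_fraction > 0:
            uid = f"UniRef50_AM_{fam.name}"
            acc = f"{uid}_A1"
            add_annotation(
                ProteinAnnotation(
                    accession=acc,
                    uniref50_id=uid,
                    tax_id=species_tax[fam.name],
                    keywords=frozenset({("", "Antimicrobial")}),
                    description="Lysozyme",
                )
            )
            entries.append(
                _Entry("antimicrobial", fam.name, uid,
                       base * spec.antimicrobial_fraction, (acc,))
            )
        # phage metaproteins: one taxonomically placed under Viruses, one
        # resolving only to root (recognised by its description).  The load
        # is defined relative to the family-assigned microbial spectra (the
        # denominator of the measured phage fraction), so the expected
        # measured ratio equals the configured load.
        load = spec.phage_load.get(fam.name, 0.0)
        if load > 0:
            at_family_w = sum(
                e.weight
                for e in entries
                if e.family == fam.name and e.at_family
                and e.kind in ("microbial", "crispr", "antimicrobial")
            )
            phage_w = at_family_w * load
            virus_id = next_id
            nodes[virus_id] = TaxonomyNode(
                virus_id, VIRUSES_ID, "species", f"{fam.genus} phage vB01"
            )
            next_id += 10
            uid = f"UniRef50_PHT_{fam.name}"
            acc = f"{uid}_A1"
            add_annotation(
                ProteinAnnotation(
                    accession=acc, uniref50_id=uid, tax_id=virus_id,
                    description=f"{fam.genus} phage vB01 tail fiber protein",
                )
            )
            entries.append(
                _Entry("phage", fam.name, uid,
                       phage_w * (1 - spec.root_phage_share), (acc,))
            )
            uid = f"UniRef50_PHR_{fam.name}"
            acc = f"{uid}_A1"
            add_annotation(
                ProteinAnnotation(
                    accession=acc, uniref50_id=uid, tax_id=None,
                    description=f"{fam.genus} phage major capsid protein",
                )
            )
            entries.append(
                _Entry("phage", fam.name, uid,
                       phage_w * spec.root_phage_share, (acc,))
            )

    tree = TaxonomyTree(nodes=nodes, root_id=ROOT_ID)
    return Reference(
        annotations=annotations, tree=tree, entries=entries,
        family_tax=family_tax,
    )


# ---------------------------------------------------------------------------
# PSM simulation


@dataclass
class GroundTruth:
    expected_family_fractions: dict[str, float]  # microbial family shares
    phage_load: dict[str, float]
    sample_plant: dict[str, str]
    plant_type: dict[str, str]
    per_sample_weights: dict[str, np.ndarray]
    entry_index: list[_Entry]
    false_accessions: set[str]


@dataclass
class SimulationResult:
    psm_sets: dict[tuple[str, str], SearchResultSet]  # (sample, engine)
    truth: GroundTruth
    reference: Reference

    @property
    def samples(self) -> list[str]:
        return sorted({s for s, _ in self.psm_sets})


def _peptide(index: int, variant: int) -> str:
    value = index * 7 + variant
    letters = []
    for _ in range(8):
        letters.append(_AMINO[value % len(_AMINO)])
        value //= len(_AMINO)
    return "".join(letters)


def _plant_type_cycle(config: SimulationConfig) -> list[str]:
    base = config.plant_types or ("mixotrophic", "strictly_hydrogenotrophic")
    return [base[i % len(base)] for i in range(config.n_plants)]


def _perturb(rng: np.random.Generator, w: np.ndarray, conc: float | None) -> np.ndarray:
    if conc is None or not math.isfinite(conc):
        return w
    return rng.dirichlet(w * conc + 1e-9)


_TYPE_MODIFIER = {
    "mixotrophic": {"acetoclastic": 1.0, "acds_bacterial": 0.3},
    "strictly_hydrogenotrophic": {"acetoclastic": 0.02, "acds_bacterial": 3.0},
}


def simulate_psms(
    spec: CommunitySpec, config: SimulationConfig
) -> SimulationResult:
    """Draw PSM tables for every plant x time point x technical replicate.

    Hierarchical noise: one Dirichlet draw per plant (between-plant
    variation, shaped by the plant's methanogenesis type), one per time
    point, one per technical replicate; spectra are multinomial at
    ``spectra_depth``.  Decoy records (and optional entrapment false
    targets) are appended per engine with left-shifted scores.
    """
    reference = build_reference(spec)
    rng = np.random.default_rng(config.seed)
    entries = reference.entries
    base_w = np.array([e.weight for e in entries])
    base_w = base_w / base_w.sum()
    family_names = sorted({e.family for e in entries})
    fam_of = np.array([family_names.index(e.family) for e in entries])

    def _family_scaled(w: np.ndarray, fam_target: np.ndarray) -> np.ndarray:
        """Rescale entry weights so family totals match ``fam_target``;
        within-family composition (and hence phage:host ratios) is kept."""
        fam_now = np.bincount(fam_of, weights=w, minlength=len(family_names))
        scaled = w * (fam_target / fam_now)[fam_of]
        return scaled / scaled.sum()

    plant_types = _plant_type_cycle(config)
    psm_sets: dict[tuple[str, str], SearchResultSet] = {}
    per_sample_weights: dict[str, np.ndarray] = {}
    sample_plant: dict[str, str] = {}
    plant_type: dict[str, str] = {}
    false_accessions: set[str] = set()

    t_mean, t_sd = config.target_score
    d_mean, d_sd = config.decoy_score

    for p in range(config.n_plants):
        plant = f"BGP{p + 1:02d}"
        modifier = _TYPE_MODIFIER[plant_types[p]]
        plant_type[plant] = plant_types[p]
        w_plant = base_w * np.array(
            [modifier.get(e.tag, 1.0) if e.tag else 1.0 for e in entries]
        )
        w_plant = w_plant / w_plant.sum()
        # compositional noise acts on family totals; phages track their hosts
        fam_base = np.bincount(fam_of, weights=w_plant,
                               minlength=len(family_names))
        fam_plant = _perturb(rng, fam_base, config.plant_concentration)
        for t in range(config.time_points):
            fam_time = _perturb(rng, fam_plant, config.time_concentration)
            for r in range(config.technical_replicates):
                sample = f"{plant}_T{t + 1}_R{r + 1}"
                sample_plant[sample] = plant
                fam_rep = _perturb(rng, fam_time,
                                   config.dirichlet_concentration)
                w = _family_scaled(w_plant, fam_rep)
                per_sample_weights[sample] = w
                counts = rng.multinomial(config.spectra_depth, w)
                records_by_engine: dict[str, list[PsmRecord]] = {
                    e: [] for e in config.engines
                }
                scan = 0
                for entry_idx, count in enumerate(counts):
                    entry = entries[entry_idx]
                    for j in range(count):
                        scan += 1
                        key = f"{sample}_scan{scan:06d}"
                        peptide = _peptide(entry_idx, j % 3)
                        detected = rng.random(len(config.engines))
                        for ei, engine in enumerate(config.engines):
                            if detected[ei] > config.engine_detection_prob:
                                continue
                            records_by_engine[engine].append(
                                PsmRecord(
                                    spectrum_key=key,
                                    sample_id=sample,
                                    engines=(engine,),
                                    peptide=peptide,
                                    score=float(rng.normal(t_mean, t_sd)),
                                    accessions=entry.accessions,
                                    is_decoy=False,
                                )
                            )
                n_decoy = int(round(config.decoy_fraction * config.spectra_depth))
                n_false = int(
                    round(config.false_target_fraction * config.spectra_depth)
                )
                for engine in config.engines:
                    recs = records_by_engine[engine]
                    for j in range(n_decoy):
                        recs.append(
                            PsmRecord(
                                spectrum_key=f"{sample}_{engine}_decoy{j:06d}",
                                sample_id=sample,
                                engines=(engine,),
                                peptide=_peptide(900_000 + j, 0),
                                score=float(rng.normal(d_mean, d_sd)),
                                accessions=(f"DECOY_{j:06d}",),
                                is_decoy=True,
                            )
                        )
                    for j in range(n_false):
                        acc = f"FALSE_{j:06d}"
                        false_accessions.add(acc)
                        recs.append(
                            PsmRecord(
                                spectrum_key=f"{sample}_{engine}_false{j:06d}",
                                sample_id=sample,
                                engines=(engine,),
                                peptide=_peptide(800_000 + j, 0),
                                score=float(rng.normal(d_mean, d_sd)),
                                accessions=(acc,),
                                is_decoy=False,
                            )
                        )
                    psm_sets[(sample, engine)] = SearchResultSet(records=recs)

    microbial = sum(
        e.weight for e in entries if e.kind in ("microbial", "crispr",
                                                "antimicrobial")
    )
    expected = {}
    for fam in spec.families:
        fam_w = sum(
            e.weight
            for e in entries
            if e.family == fam.name
            and e.kind in ("microbial", "crispr", "antimicrobial")
        )
        expected[fam.name] = fam_w / microbial
    truth = GroundTruth(
        expected_family_fractions=expected,
        phage_load=dict(spec.phage_load),
        sample_plant=sample_plant,
        plant_type=plant_type,
        per_sample_weights=per_sample_weights,
        entry_index=entries,
        false_accessions=false_accessions,
    )
    return SimulationResult(psm_sets=psm_sets, truth=truth, reference=reference)


# ---------------------------------------------------------------------------
# End-to-end recovery


def end_to_end_recovery(
    spec: CommunitySpec, config: SimulationConfig
) -> dict:
    """Run the full pipeline on a simulated study and score it against truth.

    Reports family-fraction recovery (max absolute error and error in
    multinomial standard-error units), per-family phage-per-cell estimates
    against the volume-scaled generator loads, methanogenesis-type calls per
    plant, and whether every technical-replicate pair merges before any
    cross-plant merge in the dendrogram.
    """
    from . import adm1 as adm1_mod
    from .metaproteins import build_metaproteins
    from .phage_defense import phage_host_table, phages_per_cell
    from .profiles import cluster_samples, matrix_from_metaproteins, normalize, rollup
    from .psm_io import filter_by_fdr, merge_engines

    sim = simulate_psms(spec, config)
    filtered = [filter_by_fdr(s) for s in sim.psm_sets.values()]
    merged = merge_engines(filtered)
    metaproteins = build_metaproteins(
        merged, sim.reference.annotations, sim.reference.tree
    )
    tree = sim.reference.tree

    # taxonomic recovery: measured family share of microbial spectra against
    # the expectation implied by the realized per-sample mixture weights
    # (exact for the multinomial sampling stage, whatever the Dirichlet
    # noise did)
    records, summary = phage_host_table(metaproteins, tree)
    family_spectra = {r.family: r.family_spectra for r in records}
    microbial_total = sum(family_spectra.values())
    entries = sim.truth.entry_index
    micro_idx = [
        i for i, e in enumerate(entries)
        if e.kind in ("microbial", "crispr", "antimicrobial")
    ]
    weights = np.vstack(
        [sim.truth.per_sample_weights[s] for s in sorted(
            sim.truth.per_sample_weights)]
    )
    micro_w = weights[:, micro_idx].sum()
    errors = {}
    n_eff = microbial_total
    for fam in sim.truth.expected_family_fractions:
        fam_idx = [
            i for i in micro_idx
            if entries[i].family == fam and entries[i].at_family
        ]
        expected_at_family = weights[:, fam_idx].sum() / micro_w
        measured = family_spectra.get(fam, 0) / microbial_total
        se = math.sqrt(expected_at_family * (1 - expected_at_family) / n_eff)
        errors[fam] = {
            "expected": float(expected_at_family),
            "measured": measured,
            "abs_error": abs(measured - expected_at_family),
            "se_units": abs(measured - expected_at_family) / se if se else 0.0,
        }

    phage = {}
    for fam, load in sim.truth.phage_load.items():
        rec = next((r for r in records if r.family == fam), None)
        measured_ratio = (
            rec.phage_spectra / rec.family_spectra
            if rec and rec.family_spectra
            else 0.0
        )
        estimate = phages_per_cell(measured_ratio)
        truth_value = phages_per_cell(load)
        phage[fam] = {
            "measured_ratio": measured_ratio,
            "phages_per_cell": estimate,
            "truth": truth_value,
            "rel_error": abs(estimate - truth_value) / truth_value,
        }

    steps = adm1_mod.map_to_steps(metaproteins, adm1_mod.default_adm1_map(), tree)
    acds = adm1_mod.acds_split(metaproteins, tree)
    calls = adm1_mod.classify_methanogenesis(steps, acds)
    per_plant: dict[str, list[str]] = {}
    for call in calls:
        plant = sim.truth.sample_plant[call.sample_id]
        per_plant.setdefault(plant, []).append(call.label)
    methanogenesis = {
        plant: {
            "truth": sim.truth.plant_type[plant],
            "calls": labels,
            "correct": all(l == sim.truth.plant_type[plant] for l in labels),
        }
        for plant, labels in per_plant.items()
    }

    fractions = normalize(matrix_from_metaproteins(metaproteins))
    dendrogram = cluster_samples(fractions)
    replicate_pairs = {}
    for sample, plant in sim.truth.sample_plant.items():
        replicate_pairs.setdefault(sample.rsplit("_R", 1)[0], set()).add(sample)
    cross_plant_height = None
    pair_heights = {}
    for left, right, height in dendrogram.merges:
        plants = {sim.truth.sample_plant[s] for s in left + right}
        if len(plants) > 1 and cross_plant_height is None:
            cross_plant_height = height
        for key, pair in replicate_pairs.items():
            if pair <= set(left + right) and key not in pair_heights:
                pair_heights[key] = height
    replicates_first = cross_plant_height is None or all(
        h < cross_plant_height for h in pair_heights.values()
    )

    return {
        "family_recovery": errors,
        "phage": phage,
        "methanogenesis": methanogenesis,
        "replicates_cluster_first": bool(replicates_first),
        "summary": {
            "total_spectra": summary.total_spectra,
            "phage_share_percent": summary.phage_share_percent,
            "crispr_share_percent": summary.crispr_share_percent,
        },
    }


# ---------------------------------------------------------------------------
# File export


def write_simulation(sim: SimulationResult, out_dir) -> None:
    """Write the PSM, annotation and taxonomy fixtures a pipeline run reads."""
    import pathlib

    from .metaproteins import write_annotation_table
    from .psm_io import write_psm_table

    out = pathlib.Path(out_dir)
    (out / "psms").mkdir(parents=True, exist_ok=True)
    for (sample, engine), result_set in sorted(sim.psm_sets.items()):
        with open(out / "psms" / f"{sample}.{engine}.tsv", "w") as handle:
            write_psm_table(result_set, handle)
    with open(out / "annotations.tsv", "w") as handle:
        write_annotation_table(sim.reference.annotations, handle)
    tree = sim.reference.tree
    with open(out / "nodes.dmp", "w") as handle:
        for node in sorted(tree.nodes.values(), key=lambda n: n.tax_id):
            handle.write(
                f"{node.tax_id}\t|\t{node.parent_id}\t|\t{node.rank}\t|\n"
            )
    with open(out / "names.dmp", "w") as handle:
        for node in sorted(tree.nodes.values(), key=lambda n: n.tax_id):
            handle.write(
                f"{node.tax_id}\t|\t{node.name}\t|\t\t|\tscientific name\t|\n"
            )
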