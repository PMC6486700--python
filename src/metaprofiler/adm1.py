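"""Mapping metaproteins onto Anaerobic Digestion Model 1 process steps.

Each step of the structured anaerobic-digestion model (hydrolysis, substrate
uptake, acidogenesis/fermentation, acetogenesis, methanogenesis, one-carbon
metabolism) carries a set of EC numbers and KEGG Orthology ids plus a taxon
restriction: fermentation steps exclude archaea, methanogenesis admits only
archaea.  A metaprotein matches a step when its EC/KO annotations intersect
the step's sets and its LCA superkingdom satisfies the restriction; one
metaprotein may serve several steps.

Methanogenesis typing splits the stage into acetoclastic and
non-acetoclastic (hydrogenotrophic/methyl) spectra; a sample whose
acetoclastic share falls below a threshold (default 0.1) is called strictly
hydrogenotrophic, otherwise mixotrophic.  The archaeal-versus-bacterial
split of the acetyl-CoA decarbonylase/synthase (ACDS) complex is reported
alongside: bacterial dominance supports a syntrophic acetate-oxidation
interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import IO, Mapping, Sequence

from .metaproteins import Metaprotein
from .taxonomy import UNASSIGNED, TaxonomyTree, ancestor_at_rank

STAGES = (
    "hydrolysis",
    "substrate_uptake",
    "acidogenesis/fermentation",
    "acetogenesis",
    "methanogenesis",
    "one_carbon",
)
RESTRICTIONS = ("none", "bacteria_only", "archaea_only")

MIXOTROPHIC = "mixotrophic"
STRICTLY_HYDROGENOTROPHIC = "strictly_hydrogenotrophic"
UNCLASSIFIABLE = "unclassifiable"

#: KOs of the acetyl-CoA decarbonylase/synthase // CODH/ACS complex.
ACDS_KO_IDS = frozenset({"K00193", "K00194", "K00197"})

DEFAULT_THETA = 0.1


class Adm1ConfigError(Exception):
    pass


@dataclass(frozen=True)
class Adm1Step:
    step_id: str
    stage: str
    substrate: str
    ec_numbers: frozenset[str]
    ko_ids: frozenset[str]
    taxon_restriction: str = "none"


@dataclass
class Adm1Map:
    steps: list[Adm1Step]

    def __post_init__(self):
        seen = set()
        for step in self.steps:
            if step.step_id in seen:
                raise Adm1ConfigError(f"duplicate step_id {step.step_id!r}")
            seen.add(step.step_id)
            if not step.ec_numbers and not step.ko_ids:
                raise Adm1ConfigError(f"step {step.step_id!r} has no EC and no KO")
            if step.stage not in STAGES:
                raise Adm1ConfigError(f"unknown stage {step.stage!r}")
            if step.taxon_restriction not in RESTRICTIONS:
                raise Adm1ConfigError(
                    f"unknown restriction {step.taxon_restriction!r}"
                )

    @property
    def stages(self) -> list[str]:
        return sorted({s.stage for s in self.steps}, key=STAGES.index)


@dataclass
class StepAbundance:
    step_id: str
    stage: str
    substrate: str
    counts: dict[str, int] = field(default_factory=dict)  # sample -> spectra
    stage_fractions: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def load_adm1_map(source: IO[str]) -> Adm1Map:
    """Parse the flat TSV config (step_id, stage, substrate, ec, ko,
    restriction; EC/KO lists semicolon-joined)."""
    header = source.readline().rstrip("\n").split("\t")
    required = ("step_id", "stage", "substrate", "ec", "ko", "restriction")
    missing = [c for c in required if c not in header]
    if missing:
        raise Adm1ConfigError(f"missing column(s) {missing}")
    idx = {c: header.index(c) for c in required}
    steps = []
    for line in source:
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        fields += [""] * (len(header) - len(fields))
        steps.append(
            Adm1Step(
                step_id=fields[idx["step_id"]].strip(),
                stage=fields[idx["stage"]].strip(),
                substrate=fields[idx["substrate"]].strip(),
                ec_numbers=frozenset(
                    x.strip() for x in fields[idx["ec"]].split(";") if x.strip()
                ),
                ko_ids=frozenset(
                    x.strip() for x in fields[idx["ko"]].split(";") if x.strip()
                ),
                taxon_restriction=fields[idx["restriction"]].strip() or "none",
            )
        )
    return Adm1Map(steps=steps)


def default_adm1_map() -> Adm1Map:
    """The shipped mapping covering hydrolysis through methanogenesis."""
    ref = resources.files("metaprofiler").joinpath("data/adm1_default.tsv")
    with ref.open("r") as handle:
        return load_adm1_map(handle)


def _superkingdom(tree: TaxonomyTree, tax_id: int | None) -> str | None:
    if tax_id is None or tax_id not in tree.nodes:
        return None
    sk = ancestor_at_rank(tree, tax_id, "superkingdom")
    return None if sk is UNASSIGNED else tree.nodes[sk].name


def _satisfies(restriction: str, superkingdom: str | None) -> bool:
    if restriction == "none":
        return True
    if restriction == "bacteria_only":
        return superkingdom == "Bacteria"
    return superkingdom == "Archaea"


def map_to_steps(
    metaproteins: Sequence[Metaprotein], adm1_map: Adm1Map, tree: TaxonomyTree
) -> list[StepAbundance]:
    """Per-step spectral counts by sample, honouring taxon restrictions.

    Stage fractions are each step's share of its stage total within a
    sample (defined only where the stage total is nonzero).
    """
    abundances = {
        step.step_id: StepAbundance(
            step_id=step.step_id, stage=step.stage, substrate=step.substrate
        )
        for step in adm1_map.steps
    }
    for mp in metaproteins:
        sk = _superkingdom(tree, mp.lca_tax_id)
        for step in adm1_map.steps:
            if not (mp.ec_numbers & step.ec_numbers or mp.ko_ids & step.ko_ids):
                continue
            if not _satisfies(step.taxon_restriction, sk):
                continue
            target = abundances[step.step_id].counts
            for sample, count in mp.spectral_counts.items():
                target[sample] = target.get(sample, 0) + count

    stage_totals: dict[tuple[str, str], int] = {}
    for ab in abundances.values():
        for sample, count in ab.counts.items():
            key = (ab.stage, sample)
            stage_totals[key] = stage_totals.get(key, 0) + count
    for ab in abundances.values():
        for sample, count in ab.counts.items():
            total = stage_totals[(ab.stage, sample)]
            if total > 0:
                ab.stage_fractions[sample] = count / total
    return [abundances[s.step_id] for s in adm1_map.steps]


def coverage_report(step_abundances: Sequence[StepAbundance]) -> dict[str, dict]:
    """Present/absent flags per step, grouped by stage.

    A step is absent when its total spectra across all samples is zero —
    the study-level statement "no evidence for X" corresponds to an absent
    step.
    """
    report: dict[str, dict] = {}
    for ab in step_abundances:
        stage = report.setdefault(ab.stage, {"present": [], "absent": []})
        stage["present" if ab.total > 0 else "absent"].append(ab.step_id)
    return report


def acds_split(
    metaproteins: Sequence[Metaprotein],
    tree: TaxonomyTree,
    ko_ids: frozenset[str] = ACDS_KO_IDS,
) -> dict[str, dict[str, int]]:
    """Archaeal vs bacterial ACDS/CODH-ACS spectral counts per sample."""
    split: dict[str, dict[str, int]] = {}
    for mp in metaproteins:
        if not (mp.ko_ids & ko_ids):
            continue
        sk = _superkingdom(tree, mp.lca_tax_id)
        if sk == "Archaea":
            bucket = "archaeal"
        elif sk == "Bacteria":
            bucket = "bacterial"
        else:
            continue
        for sample, count in mp.spectral_counts.items():
            per = split.setdefault(sample, {"archaeal": 0, "bacterial": 0})
            per[bucket] += count
    return split


@dataclass
class MethanogenesisCall:
    sample_id: str
    label: str
    acetoclastic_share: float | None
    methanogenesis_spectra: int
    acds_archaeal: int = 0
    acds_bacterial: int = 0


def classify_methanogenesis(
    step_abundances: Sequence[StepAbundance],
    acds: Mapping[str, Mapping[str, int]] | None = None,
    theta: float = DEFAULT_THETA,
) -> list[MethanogenesisCall]:
    """Type each sample's methanogenesis as mixotrophic or strictly
    hydrogenotrophic.

    The acetoclastic share is the acetate-substrate fraction of the
    methanogenesis stage; a share below ``theta`` means strictly
    hydrogenotrophic.  Samples with zero methanogenesis spectra are
    unclassifiable.
    """
    meth = [ab for ab in step_abundances if ab.stage == "methanogenesis"]
    samples = sorted({s for ab in step_abundances for s in ab.counts})
    acds = acds or {}
    calls = []
    for sample in samples:
        total = sum(ab.counts.get(sample, 0) for ab in meth)
        aceto = sum(
            ab.counts.get(sample, 0) for ab in meth if ab.substrate == "acetate"
        )
        if total == 0:
            label, share = UNCLASSIFIABLE, None
        else:
            share = aceto / total
            label = STRICTLY_HYDROGENOTROPHIC if share < theta else MIXOTROPHIC
        per = acds.get(sample, {})
        calls.append(
            MethanogenesisCall(
                sample_id=sample,
                label=label,
                acetoclastic_share=share,
                methanogenesis_spectra=total,
                acds_archaeal=per.get("archaeal", 0),
                acds_bacterial=per.get("bacterial", 0),
            )
        )
    return calls


def write_step_csv(step_abundances: Sequence[StepAbundance], sink: IO[str]) -> None:
    samples = sorted({s for ab in step_abundances for s in ab.counts})
    sink.write(",".join(["step_id", "stage", "substrate"] + samples) + "\n")
    for ab in step_abundances:
        row = [ab.step_id, ab.stage, ab.substrate]
        row += [str(ab.counts.get(s, 0)) for s in samples]
        sink.write(",".join(row) + "\n")
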