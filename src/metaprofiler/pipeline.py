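"""End-to-end orchestration: filter -> merge -> group -> annotate ->
profiles -> phage -> ADM1 -> cluster, with a run manifest per output."""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
from dataclasses import asdict, dataclass

from . import __version__, adm1 as adm1_mod
from .metaproteins import (
    build_metaproteins,
    read_annotation_table,
    write_metaprotein_csv,
)
from .phage_defense import (
    PhageBurdenParams,
    phage_host_table,
    write_phage_host_csv,
)
from .profiles import (
    chord_matrix,
    cluster_samples,
    joint_family_process_counts,
    krona_rows,
    matrix_from_metaproteins,
    normalize,
    rollup,
    write_krona,
)
from .psm_io import filter_by_fdr, merge_engines, read_psm_table
from .taxonomy import load_taxonomy

logger = logging.getLogger("metaprofiler")


class PipelineConfigError(Exception):
    pass


@dataclass
class PipelineConfig:
    psm_dir: str
    annotations: str
    taxonomy_nodes: str
    taxonomy_names: str
    out_dir: str
    adm1_map: str | None = None
    overrides: str | None = None
    fdr_target: float = 0.01
    chord_k: int = 20
    cell_diameter_um: float = 1.0
    phage_diameter_um: float = 0.1
    theta: float = 0.1
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Flat key=value config text; '#' starts a comment line."""
        values: dict[str, str] = {}
        for line in pathlib.Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            values[key.strip()] = value.strip()
        required = ("psm_dir", "annotations", "taxonomy_nodes",
                    "taxonomy_names", "out_dir")
        missing = [k for k in required if k not in values]
        if missing:
            raise PipelineConfigError(f"missing config key(s): {missing}")
        kwargs: dict = {k: values[k] for k in required}
        for key, cast in (
            ("adm1_map", str), ("overrides", str), ("fdr_target", float),
            ("chord_k", int), ("cell_diameter_um", float),
            ("phage_diameter_um", float), ("theta", float), ("alpha", float),
            ("seed", int),
        ):
            if key in values:
                kwargs[key] = cast(values[key])
        return cls(**kwargs)

    def validate(self) -> None:
        for key in ("psm_dir", "annotations", "taxonomy_nodes",
                    "taxonomy_names"):
            path = getattr(self, key)
            if not pathlib.Path(path).exists():
                raise PipelineConfigError(f"{key} path does not exist: {path}")
        if not 0 < self.fdr_target <= 1:
            raise PipelineConfigError("fdr_target must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise PipelineConfigError("alpha must be in (0, 1)")


ARTIFACTS = (
    "metaproteins.csv",
    "family_profile.csv",
    "process_profile.csv",
    "krona.txt",
    "chord.csv",
    "phage_table.csv",
    "adm1_steps.csv",
    "dendrogram.nwk",
    "report.json",
)


def _sha256(path: pathlib.Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def _write_matrix_csv(matrix, path: pathlib.Path) -> None:
    matrix.data.to_csv(path, index_label="entity")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the artifact bundle plus a manifest.

    Returns the report dictionary (global phage/CRISPR summary, ADM1
    coverage and methanogenesis calls).  Any stage failure raises with the
    stage name in the message; inputs are never mutated.
    """
    config.validate()
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage: %s", name)

    inputs: dict[str, str] = {}

    stage("filter")
    psm_dir = pathlib.Path(config.psm_dir)
    psm_paths = sorted(psm_dir.glob("*.tsv"))
    if not psm_paths:
        raise PipelineConfigError(f"no PSM tables under {psm_dir}")
    filtered = []
    for path in psm_paths:
        inputs[str(path)] = _sha256(path)
        with open(path) as handle:
            filtered.append(filter_by_fdr(read_psm_table(handle),
                                          config.fdr_target))

    stage("merge")
    merged = merge_engines(filtered)

    stage("group")
    annotations_path = pathlib.Path(config.annotations)
    inputs[str(annotations_path)] = _sha256(annotations_path)
    with open(annotations_path) as handle:
        annotations = read_annotation_table(handle)
    for key in ("taxonomy_nodes", "taxonomy_names"):
        inputs[getattr(config, key)] = _sha256(pathlib.Path(getattr(config, key)))
    with open(config.taxonomy_nodes) as nodes, open(config.taxonomy_names) as names:
        tree = load_taxonomy(nodes, names)

    stage("annotate")
    metaproteins = build_metaproteins(merged, annotations, tree)
    with open(out / "metaproteins.csv", "w") as handle:
        write_metaprotein_csv(metaproteins, tree, handle)

    stage("profiles")
    family = rollup(metaproteins, tree, "family")
    process = rollup(metaproteins, tree, "biological-process")
    _write_matrix_csv(normalize(family), out / "family_profile.csv")
    _write_matrix_csv(normalize(process), out / "process_profile.csv")
    with open(out / "krona.txt", "w") as handle:
        write_krona(krona_rows(metaproteins, tree), handle)
    chord = chord_matrix(
        family, process, joint_family_process_counts(metaproteins, tree),
        k=config.chord_k,
    )
    chord.cells.to_csv(out / "chord.csv", index_label="family")

    stage("phage")
    overrides = None
    if config.overrides:
        overrides = {}
        path = pathlib.Path(config.overrides)
        inputs[str(path)] = _sha256(path)
        for line in path.read_text().splitlines()[1:]:
            if line.strip():
                virus, _, host = line.partition("\t")
                overrides[virus.strip()] = host.strip()
    records, summary = phage_host_table(metaproteins, tree, overrides)
    with open(out / "phage_table.csv", "w") as handle:
        write_phage_host_csv(records, handle)

    stage("adm1")
    if config.adm1_map:
        path = pathlib.Path(config.adm1_map)
        inputs[str(path)] = _sha256(path)
        with open(path) as handle:
            adm1_map = adm1_mod.load_adm1_map(handle)
    else:
        adm1_map = adm1_mod.default_adm1_map()
    steps = adm1_mod.map_to_steps(metaproteins, adm1_map, tree)
    with open(out / "adm1_steps.csv", "w") as handle:
        adm1_mod.write_step_csv(steps, handle)
    acds = adm1_mod.acds_split(metaproteins, tree)
    calls = adm1_mod.classify_methanogenesis(steps, acds, config.theta)

    stage("cluster")
    fractions = normalize(matrix_from_metaproteins(metaproteins))
    newick = cluster_samples(fractions).to_newick()
    (out / "dendrogram.nwk").write_text(newick + "\n")

    burden_params = PhageBurdenParams(
        cell_diameter_um=config.cell_diameter_um,
        phage_diameter_um=config.phage_diameter_um,
    )
    report = {
        "n_metaproteins": len(metaproteins),
        "n_samples": len(fractions.column_ids),
        "total_spectra": summary.total_spectra,
        "phage_share_percent": summary.phage_share_percent,
        "crispr_share_percent": summary.crispr_share_percent,
        "adm1_coverage": adm1_mod.coverage_report(steps),
        "methanogenesis": {
            c.sample_id: {
                "label": c.label,
                "acetoclastic_share": c.acetoclastic_share,
                "acds_archaeal": c.acds_archaeal,
                "acds_bacterial": c.acds_bacterial,
            }
            for c in calls
        },
        "burden_params": asdict(burden_params),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")

    manifest = {
        "version": __version__,
        "parameters": asdict(config),
        "inputs": inputs,
        "artifacts": list(ARTIFACTS),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return report
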