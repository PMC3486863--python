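"""End-to-end pipeline: taxonomy → vetting → census → mapping → report.

A YAML config (schema-validated) names the inputs and thresholds; the
pipeline runs each stage, writes its tabular outputs, and finishes with a
manifest recording the stages completed, SHA-256 of every input consumed,
the seed, and the package version — enough to audit or byte-reproduce a
run. Any stage failure aborts with a stage-tagged error; outputs written
by earlier stages are left in place.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field, ValidationError

from . import __version__
from . import census as census_mod
from . import discovery as discovery_mod
from . import phylo as phylo_mod
from . import taxonomy as taxonomy_mod
from . import vetting as vetting_mod
from .taxonomy import DOMAINS_OF_LIFE, UNASSIGNED

logger = logging.getLogger(__name__)


class TaxonomyInputs(BaseModel):
    nodes: str
    names: str | None = None
    config: str | None = None


class PipelineConfig(BaseModel):
    annotations: str
    families: str
    taxonomy: TaxonomyInputs
    out_dir: str
    tree: str | None = None
    tip_taxa: str | None = None
    seed: int = 0
    margin: float = Field(default=10.0, ge=0)
    broad_threshold: float = Field(default=0.5, gt=0, le=1)
    clade_coverage: float = Field(default=0.5, gt=0, le=1)
    max_losses: int | None = None
    vet_all: bool = False
    level: str = "FAMILY"
    exclude_units: list[str] = Field(default_factory=list)
    run_discovery: bool = True


class PipelineStageError(RuntimeError):
    """An error raised inside a named stage, tagged for the operator."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class ConfigError(ValueError):
    pass


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        fields = ", ".join(
            ".".join(str(p) for p in err["loc"]) for err in exc.errors()
        )
        raise ConfigError(f"invalid pipeline config (fields: {fields})") from exc


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def bias_profile(
    records: pd.DataFrame, assignments: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Annotation counts per (domain, division) and the per-domain
    skewness summary: the fraction of the domain's annotations held by
    its single most-annotated division. Under an even spread this tends
    to 1/n_divisions; under strong database bias it approaches 1."""
    amap = assignments.set_index("taxon_id")
    merged = records.merge(
        amap[["domain", "division"]], left_on="taxon_id", right_index=True, how="left"
    )
    merged[["domain", "division"]] = merged[["domain", "division"]].fillna(UNASSIGNED)
    counts = (
        merged.groupby(["domain", "division"], sort=True)
        .size()
        .rename("n_annotations")
        .reset_index()
    )
    top_fraction: dict[str, float] = {}
    for dom, grp in counts[counts["division"] != UNASSIGNED].groupby("domain"):
        tot = grp["n_annotations"].sum()
        if tot:
            top_fraction[str(dom)] = float(grp["n_annotations"].max() / tot)
    return counts, top_fraction


def run_pipeline(config: PipelineConfig | str | Path) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    if not isinstance(config, PipelineConfig):
        config = load_pipeline_config(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages_done: list[str] = []
    inputs: dict[str, str] = {}

    def record_input(name: str, path: str | None) -> None:
        if path is not None:
            inputs[name] = _sha256(path)

    # -- taxonomy ---------------------------------------------------------
    try:
        record_input("annotations", config.annotations)
        record_input("families", config.families)
        record_input("taxonomy_nodes", config.taxonomy.nodes)
        record_input("taxonomy_names", config.taxonomy.names)
        record_input("taxonomy_config", config.taxonomy.config)
        index = taxonomy_mod.load_taxonomy(
            config.taxonomy.nodes, config.taxonomy.names, config.taxonomy.config
        )
        annotations = vetting_mod.read_annotations(config.annotations)
        families = vetting_mod.read_families(config.families)
        assignments = taxonomy_mod.assign_table(index, annotations["taxon_id"])
        taxonomy_mod.write_assignments(assignments, out / "assignments.tsv")
    except Exception as exc:  # noqa: BLE001 - stage-tagged re-raise
        raise PipelineStageError("taxonomy", exc) from exc
    stages_done.append("taxonomy")
    n_unassigned = int((assignments["domain"] == UNASSIGNED).sum())
    logger.info("taxonomy: %d taxa, %d unassigned", len(assignments), n_unassigned)

    # -- vetting ----------------------------------------------------------
    try:
        domain_of = dict(zip(assignments["taxon_id"], assignments["domain"]))
        vet_config = vetting_mod.VetConfig(margin=config.margin)
        vetted, _per_family, vet_total = vetting_mod.vet_table(
            annotations, families, domain_of, vet_config, vet_all=config.vet_all
        )
        vetted.to_csv(out / "vetted_annotations.tsv", sep="\t", index=False)
        vetting_mod.write_vet_report(vet_total, out / "vet_report.json")
    except Exception as exc:
        raise PipelineStageError("vetting", exc) from exc
    stages_done.append("vetting")
    logger.info(
        "vetting: %d in, %d kept, %d dropped (margin), %d dropped (misannotation)",
        len(annotations), vet_total.kept,
        vet_total.dropped_margin, vet_total.dropped_misannotation,
    )

    # -- census -----------------------------------------------------------
    try:
        clan_map = {
            acc: m.clan_accession
            for acc, m in families.items()
            if m.clan_accession is not None
        }
        level = config.level
        kwargs = {"clan_map": clan_map} if level == "CLAN" else {}
        dom_matrix = census_mod.build_presence(
            vetted, assignments, level=level, **kwargs
        )
        if config.exclude_units:
            dom_matrix = dom_matrix.drop_units(config.exclude_units)
        dom_matrix.to_tsv(out / "presence_domains.tsv")
        venn = census_mod.venn_partition(dom_matrix)
        (out / "venn.json").write_text(json.dumps(venn.to_json_dict(), indent=2) + "\n")
        inter = census_mod.interdomain_units(dom_matrix)
        (out / "interdomain.json").write_text(
            json.dumps(
                {"interdomain": inter.interdomain, "virus_shared": inter.virus_shared},
                indent=2,
            )
            + "\n"
        )
        rates: dict[str, dict] = {}
        all_calls = []
        for dom in DOMAINS_OF_LIFE:
            divisions = index.divisions_of(dom)
            if not divisions:
                continue
            div_matrix = census_mod.build_presence(
                vetted, assignments, level=level, domain=dom, columns=divisions,
                **kwargs,
            )
            if config.exclude_units:
                div_matrix = div_matrix.drop_units(config.exclude_units)
            calls = census_mod.broad_distribution(
                div_matrix, threshold=config.broad_threshold, domain=dom
            )
            all_calls.extend(calls)
            eligible = [c for c in calls if c.divisions_present >= 1]
            if eligible:
                frac, pct = census_mod.broad_distribution_rate(calls)
                rates[dom] = {
                    "broad": sum(c.broad for c in eligible),
                    "total": len(eligible),
                    "fraction": frac,
                    "percent": pct,
                }
        census_mod.broad_calls_frame(all_calls).to_csv(
            out / "broad_calls.tsv", sep="\t", index=False
        )
        (out / "broad_rates.json").write_text(json.dumps(rates, indent=2) + "\n")
        counts, top_fraction = bias_profile(vetted, assignments)
        counts.to_csv(out / "bias_profile.tsv", sep="\t", index=False)
        (out / "bias_top_fraction.json").write_text(
            json.dumps(top_fraction, indent=2) + "\n"
        )
    except Exception as exc:
        raise PipelineStageError("census", exc) from exc
    stages_done.append("census")

    # -- phylogenetic mapping (optional) ----------------------------------
    if config.tree is not None:
        try:
            record_input("tree", config.tree)
            record_input("tip_taxa", config.tip_taxa)
            tip_taxa = (
                phylo_mod.read_tip_taxa(config.tip_taxa) if config.tip_taxa else {}
            )
            tree = phylo_mod.SpeciesTree.from_newick(
                config.tree, tip_taxa=tip_taxa, force_rooted=True
            )
            unit_presence = phylo_mod.unit_tip_presence(vetted, tip_taxa)
            nominated = phylo_mod.nominate_candidates(
                tree,
                unit_presence,
                max_losses=config.max_losses,
                clade_coverage=config.clade_coverage,
            )
            phylo_mod.reconstruction_frame(tree, unit_presence, nominated).to_csv(
                out / "dollo.tsv", sep="\t", index=False
            )
        except Exception as exc:
            raise PipelineStageError("phylo_mapping", exc) from exc
        stages_done.append("phylo_mapping")

    # -- discovery curves (optional) ---------------------------------------
    if config.run_discovery:
        try:
            dates = discovery_mod.family_dates(families, annotations)
            classes = discovery_mod.classes_from_matrix(dom_matrix)
            curves = discovery_mod.discovery_curve(dates, classes)
            discovery_mod.curves_frame(curves).to_csv(
                out / "discovery_curves.tsv", sep="\t", index=False
            )
        except Exception as exc:
            raise PipelineStageError("discovery", exc) from exc
        stages_done.append("discovery")

    manifest = {
        "stages": stages_done,
        "inputs_sha256": inputs,
        "seed": config.seed,
        "version": __version__,
        "n_annotations_in": int(len(annotations)),
        "n_annotations_vetted": int(vet_total.kept),
        "n_taxa_unassigned": n_unassigned,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
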