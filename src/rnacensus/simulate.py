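"""Synthetic Rfam-style inputs with known ground truth.

The simulator emits everything the census pipeline reads — a taxonomy
dump, a division-mapping config, a rooted species tree, a tip-to-taxon
map, and annotation/family tables — generated from an explicit
evolutionary model so that every downstream call can be scored against
truth:

* three domains, each split into major divisions, each division holding a
  caterpillar clade of taxa (polytomies at the domain and root levels);
* each family belongs to one of three classes: DOMAIN_SPECIFIC (gained at
  a domain or division node), LUCA_VERTICAL (gained at the root), or
  HGT_INTERDOMAIN (gained in one domain, transferred into at least one
  other);
* Dollo-style losses prune whole subtrees below the gain with a
  per-branch probability;
* annotations are sampled per present taxon with division-level sampling
  weights (a Dirichlet draw whose concentration shrinks as
  ``sampling_bias`` grows, emulating database skew toward well-studied
  groups);
* true hits score comfortably above the family's seed cutoff
  (exponential offset above cutoff+margin); false positives land in the
  marginal window [cutoff, cutoff+margin) in a foreign domain, so the
  bitscore-margin filter is perfectly separating at default noise.

Everything is reproducible from the seed: identical params give
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .census import PresenceMatrix
from .taxonomy import DOMAINS_OF_LIFE
from .vetting import ANNOTATION_COLUMNS

DOMAIN_SPECIFIC = "DOMAIN_SPECIFIC"
LUCA_VERTICAL = "LUCA_VERTICAL"
HGT_INTERDOMAIN = "HGT_INTERDOMAIN"
CLASSES = (DOMAIN_SPECIFIC, LUCA_VERTICAL, HGT_INTERDOMAIN)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class BitscoreModel:
    """cutoffs are drawn per family from ``cutoff_range``; true hits score
    cutoff + margin + Exp(true_offset_scale); false hits score uniformly
    in [cutoff, cutoff + margin)."""

    cutoff_range: tuple[float, float] = (25.0, 55.0)
    true_offset_scale: float = 15.0
    margin: float = 10.0


@dataclass(frozen=True)
class SimulationParams:
    seed: int = 0
    divisions_per_domain: int = 6
    taxa_per_division: int = 8
    n_families: int = 60
    class_mix: tuple[float, float, float] = (0.8, 0.1, 0.1)  # order CLASSES
    loss_prob: float = 0.1
    hgt_rate: float = 0.5  # expected transfers beyond the first
    fp_rate: float = 0.2
    fp_misannotated_frac: float = 0.25
    bitscore_model: BitscoreModel = field(default_factory=BitscoreModel)
    sampling_bias: float = 0.0
    detect_prob: float = 0.95
    annotation_rate: float = 2.0  # extra annotations per detected taxon (Poisson)
    viruses: bool = True
    n_viral_taxa: int = 8
    viral_share_prob: float = 0.0
    broad_gain_prob: float = 0.5  # P(domain-specific family gained at domain root)

    def __post_init__(self) -> None:
        if self.taxa_per_division < 1 or self.divisions_per_domain < 1:
            raise ConfigurationError("need at least one division and one taxon each")
        if self.n_families < 1:
            raise ConfigurationError("need at least one family")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ConfigurationError("class_mix must sum to 1")
        for name in ("loss_prob", "fp_rate", "fp_misannotated_frac", "detect_prob",
                     "viral_share_prob", "broad_gain_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.hgt_rate < 0 or self.sampling_bias < 0 or self.annotation_rate < 0:
            raise ConfigurationError("rates must be non-negative")


@dataclass(frozen=True)
class FamilyTruth:
    accession: str
    klass: str
    domains: tuple[str, ...]  # domains of life with surviving presence
    gain_node: str
    losses: tuple[str, ...]  # pruned subtree roots
    hgt_events: tuple[tuple[str, str], ...]  # (target domain, recipient node)
    present_taxa: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.klass == DOMAIN_SPECIFIC and len(self.domains) != 1:
            raise ValueError("DOMAIN_SPECIFIC truth must have exactly one domain")
        if self.klass == LUCA_VERTICAL and self.gain_node != "LUCA":
            raise ValueError("LUCA_VERTICAL truth must gain at the root")


@dataclass
class SimulatedDataset:
    params: SimulationParams
    taxonomy_nodes: pd.DataFrame  # taxon_id, parent_id, rank, name
    taxonomy_config: dict
    newick: str
    tip_taxa: dict[str, int]
    annotations: pd.DataFrame
    families: pd.DataFrame
    truth: dict[str, FamilyTruth]

    def truth_interdomain(self) -> list[str]:
        return sorted(a for a, t in self.truth.items() if len(t.domains) >= 2)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "taxonomy": out / "taxonomy.tsv",
            "taxonomy_config": out / "taxonomy_config.yaml",
            "tree": out / "tree.nwk",
            "tip_taxa": out / "tip_taxa.tsv",
            "annotations": out / "annotations.tsv",
            "families": out / "families.tsv",
            "truth": out / "truth.json",
        }
        self.taxonomy_nodes.to_csv(paths["taxonomy"], sep="\t", index=False)
        paths["taxonomy_config"].write_text(
            yaml.safe_dump(self.taxonomy_config, sort_keys=True)
        )
        paths["tree"].write_text(self.newick + "\n")
        pd.DataFrame(
            sorted(self.tip_taxa.items()), columns=["tip", "taxon_id"]
        ).to_csv(paths["tip_taxa"], sep="\t", index=False)
        self.annotations.to_csv(paths["annotations"], sep="\t", index=False)
        self.families.to_csv(paths["families"], sep="\t", index=False)
        paths["truth"].write_text(
            json.dumps({a: asdict(t) for a, t in sorted(self.truth.items())}, indent=1)
            + "\n"
        )
        return paths


# -- tree construction ----------------------------------------------------


def _build_tree(params: SimulationParams):
    """Children map, division node per (domain, index), tip names.

    Root LUCA is a polytomy of the three domains; each domain a polytomy
    of its divisions; each division a caterpillar of its taxa. All
    internal nodes are named so gain/loss events are addressable.
    """
    children: dict[str, list[str]] = {"LUCA": []}
    division_node: dict[str, str] = {}
    tip_names: list[str] = []
    for dom in DOMAINS_OF_LIFE:
        children["LUCA"].append(dom)
        children[dom] = []
        for d in range(1, params.divisions_per_domain + 1):
            div = f"{dom}_D{d}"
            tips = [f"{div}_T{t}" for t in range(1, params.taxa_per_division + 1)]
            tip_names.extend(tips)
            if len(tips) == 1:
                # a one-taxon division is just its tip
                children[dom].append(tips[0])
                children[tips[0]] = []
                division_node[div] = tips[0]
                continue
            cur = tips[0]
            children[cur] = []
            for j, tip in enumerate(tips[1:], start=1):
                children[tip] = []
                inner = div if j == len(tips) - 1 else f"{div}_n{j}"
                children[inner] = [cur, tip]
                cur = inner
            children[dom].append(cur)
            division_node[div] = cur
    return children, division_node, tip_names


def _newick(children: Mapping[str, list[str]], node: str) -> str:
    if not children[node]:
        return node
    inner = ",".join(_newick(children, c) for c in children[node])
    return f"({inner}){node}"


def _leafset(children: Mapping[str, list[str]], node: str) -> list[str]:
    out, stack = [], [node]
    while stack:
        n = stack.pop()
        if children[n]:
            stack.extend(reversed(children[n]))
        else:
            out.append(n)
    return out


def _prune(
    rng: np.random.Generator,
    children: Mapping[str, list[str]],
    node: str,
    loss_prob: float,
) -> tuple[list[str], list[str]]:
    """Dollo losses below ``node``: each branch is pruned whole with
    probability ``loss_prob``. Returns (surviving tips, pruned subtree
    roots); if everything is lost the lineage is rescued by keeping one
    tip (a family must survive somewhere to be observable)."""
    survivors: list[str] = []
    losses: list[str] = []

    def walk(n: str) -> None:
        if not children[n]:
            survivors.append(n)
            return
        for c in children[n]:
            if rng.random() < loss_prob:
                losses.append(c)
            else:
                walk(c)

    walk(node)
    if not survivors:
        tips = _leafset(children, node)
        keep = tips[int(rng.integers(len(tips)))]
        return [keep], []
    return survivors, losses


# -- main entry -----------------------------------------------------------


def simulate(params: SimulationParams) -> SimulatedDataset:
    """Generate one fully reproducible dataset from ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    children, division_node, tip_names = _build_tree(params)

    # taxonomy: root=1, domains, optional Viruses, then divisions and taxa
    rows = [(1, 1, "no rank", "root")]
    next_id = 2
    domain_id: dict[str, int] = {}
    for dom in DOMAINS_OF_LIFE:
        domain_id[dom] = next_id
        rows.append((next_id, 1, "superkingdom", dom))
        next_id += 1
    viral_taxa: list[int] = []
    if params.viruses:
        virus_root = next_id
        rows.append((virus_root, 1, "superkingdom", "Viruses"))
        next_id += 1
        for v in range(1, params.n_viral_taxa + 1):
            rows.append((next_id, virus_root, "species", f"Virus_T{v}"))
            viral_taxa.append(next_id)
            next_id += 1
    tip_taxa: dict[str, int] = {}
    for dom in DOMAINS_OF_LIFE:
        for d in range(1, params.divisions_per_domain + 1):
            div = f"{dom}_D{d}"
            div_id = next_id
            rows.append((div_id, domain_id[dom], "phylum", div))
            next_id += 1
            for t in range(1, params.taxa_per_division + 1):
                tip = f"{div}_T{t}"
                rows.append((next_id, div_id, "species", tip))
                tip_taxa[tip] = next_id
                next_id += 1
    taxonomy_nodes = pd.DataFrame(
        rows, columns=["taxon_id", "parent_id", "rank", "name"]
    )
    config = {
        "domains": {d: d for d in ("Archaea", "Bacteria", "Eukaryota", "Viruses")},
        "merges": [],
        "supergroups": {
            f"Eukaryota_D{d}": f"Eukaryota_D{d}"
            for d in range(1, params.divisions_per_domain + 1)
        },
    }
    if not params.viruses:
        config["domains"].pop("Viruses")

    # division sampling weights per domain (database skew)
    ndiv = params.divisions_per_domain
    weights: dict[str, np.ndarray] = {}
    for dom in DOMAINS_OF_LIFE:
        if params.sampling_bias <= 0:
            weights[dom] = np.full(ndiv, 1.0 / ndiv)
        else:
            alpha = 1.0 / (1.0 + params.sampling_bias)
            weights[dom] = rng.dirichlet(np.full(ndiv, alpha))

    # deterministic class allocation: largest-remainder, then shuffled
    base = [int(np.floor(f * params.n_families)) for f in params.class_mix]
    rem = params.n_families - sum(base)
    fracs = sorted(
        range(len(CLASSES)),
        key=lambda i: (params.class_mix[i] * params.n_families) % 1.0,
        reverse=True,
    )
    for i in range(rem):
        base[fracs[i % len(CLASSES)]] += 1
    labels = np.array(
        [c for c, n in zip(CLASSES, base) for _ in range(n)], dtype=object
    )
    labels = labels[rng.permutation(len(labels))]

    division_nodes_of = {
        dom: [
            division_node[f"{dom}_D{d}"]
            for d in range(1, params.divisions_per_domain + 1)
        ]
        for dom in DOMAINS_OF_LIFE
    }
    bm = params.bitscore_model
    ann_rows: list[tuple] = []
    fam_rows: list[tuple] = []
    truth: dict[str, FamilyTruth] = {}
    seq_counter = 1

    def domain_of_tip(tip: str) -> str:
        return tip.split("_", 1)[0]

    for i, klass in enumerate(labels):
        acc = f"RF{i + 1:05d}"
        cutoff = float(rng.uniform(*bm.cutoff_range))
        hgt_events: list[tuple[str, str]] = []
        if klass == LUCA_VERTICAL:
            gain = "LUCA"
        elif klass == DOMAIN_SPECIFIC:
            dom = DOMAINS_OF_LIFE[int(rng.integers(3))]
            if rng.random() < params.broad_gain_prob:
                gain = dom
            else:
                gain = division_nodes_of[dom][int(rng.integers(ndiv))]
        else:  # HGT_INTERDOMAIN
            dom = DOMAINS_OF_LIFE[int(rng.integers(3))]
            gain = division_nodes_of[dom][int(rng.integers(ndiv))]
            n_transfers = 1 + int(rng.poisson(params.hgt_rate))
            others = [d for d in DOMAINS_OF_LIFE if d != dom]
            for _ in range(n_transfers):
                tdom = others[int(rng.integers(len(others)))]
                recipient = division_nodes_of[tdom][int(rng.integers(ndiv))]
                hgt_events.append((tdom, recipient))

        tips, losses = _prune(rng, children, gain, params.loss_prob)
        for _, recipient in hgt_events:
            t2, l2 = _prune(rng, children, recipient, params.loss_prob)
            tips = sorted(set(tips) | set(t2))
            losses.extend(l2)
        tips = sorted(set(tips))
        present_taxa = [tip_taxa[t] for t in tips]
        domains = tuple(sorted({domain_of_tip(t) for t in tips}))

        # annotations for present taxa, thinned by division sampling weight
        fam_year = int(rng.integers(1985, 2009))
        for tip in tips:
            dom_t = domain_of_tip(tip)
            d_idx = int(tip.split("_D")[1].split("_")[0]) - 1
            w = weights[dom_t][d_idx]
            p_detect = min(1.0, params.detect_prob * w * ndiv)
            if rng.random() >= p_detect:
                continue
            n_ann = 1 + int(rng.poisson(params.annotation_rate * w * ndiv))
            for _ in range(n_ann):
                score = cutoff + bm.margin + float(rng.exponential(bm.true_offset_scale))
                if rng.random() < 0.8:
                    y = int(rng.integers(max(1982, fam_year - 5), 2011))
                    dstr = date(y, 1 + int(rng.integers(12)), 1).isoformat()
                else:
                    dstr = ""
                ann_rows.append(
                    (f"SEQ{seq_counter:07d}", acc, tip_taxa[tip],
                     round(score, 1), "UNTESTED", dstr)
                )
                seq_counter += 1

        # optional sharing with viruses (does not change the life-domain class)
        if params.viruses and viral_taxa and rng.random() < params.viral_share_prob:
            for _ in range(1 + int(rng.integers(3))):
                vt = viral_taxa[int(rng.integers(len(viral_taxa)))]
                score = cutoff + bm.margin + float(rng.exponential(bm.true_offset_scale))
                ann_rows.append(
                    (f"SEQ{seq_counter:07d}", acc, vt, round(score, 1), "UNTESTED", "")
                )
                seq_counter += 1

        # marginal false positive in a foreign domain
        if rng.random() < params.fp_rate:
            foreign = [d for d in DOMAINS_OF_LIFE if d not in domains]
            pool: list[int] = []
            if foreign:
                fdom = foreign[int(rng.integers(len(foreign)))]
                pool = [
                    tip_taxa[t]
                    for t in sorted(tip_taxa)
                    if domain_of_tip(t) == fdom
                ]
            elif viral_taxa:
                pool = viral_taxa
            if pool:
                taxon = pool[int(rng.integers(len(pool)))]
                score = cutoff + float(rng.uniform(0.0, bm.margin))
                evid = (
                    "MISANNOTATED"
                    if rng.random() < params.fp_misannotated_frac
                    else "UNTESTED"
                )
                ann_rows.append(
                    (f"SEQ{seq_counter:07d}", acc, taxon,
                     round(min(score, cutoff + bm.margin - 0.1), 1), evid, "")
                )
                seq_counter += 1

        fam_rows.append(
            (acc, f"synthetic-{klass.lower()}-{i + 1}", "",
             round(cutoff, 1), f"Gene/synthetic/{klass}",
             date(fam_year, 1, 1).isoformat())
        )
        truth[acc] = FamilyTruth(
            accession=acc,
            klass=str(klass),
            domains=domains,
            gain_node=gain,
            losses=tuple(sorted(losses)),
            hgt_events=tuple(hgt_events),
            present_taxa=tuple(sorted(present_taxa)),
        )

    annotations = pd.DataFrame(ann_rows, columns=ANNOTATION_COLUMNS)
    families = pd.DataFrame(
        fam_rows,
        columns=["accession", "name", "clan", "seed_cutoff", "functional_path", "dates"],
    )
    newick = "[&R] " + _newick(children, "LUCA") + ";"
    return SimulatedDataset(
        params=params,
        taxonomy_nodes=taxonomy_nodes,
        taxonomy_config=config,
        newick=newick,
        tip_taxa=tip_taxa,
        annotations=annotations,
        families=families,
        truth=truth,
    )


# -- recovery scoring -----------------------------------------------------

UNDETECTED = "UNDETECTED"


@dataclass
class RecoveryScore:
    confusion: pd.DataFrame  # rows: truth class, cols: predicted
    accuracy: dict[str, float]
    misclassified: dict[str, list[str]]


def predict_class(presence_set: frozenset[str] | set[str]) -> str:
    """Distribution class implied by a domain-level presence set: one
    domain of life -> DOMAIN_SPECIFIC, two -> HGT_INTERDOMAIN, three ->
    LUCA_VERTICAL. Viruses never count toward the domain tally."""
    n = len(set(presence_set) & set(DOMAINS_OF_LIFE))
    return {0: UNDETECTED, 1: DOMAIN_SPECIFIC, 2: HGT_INTERDOMAIN, 3: LUCA_VERTICAL}[n]


def score_recovery(
    matrix: PresenceMatrix, truth: Mapping[str, FamilyTruth]
) -> RecoveryScore:
    """Confusion matrix and per-class accuracy of census classification
    against simulation ground truth."""
    if not truth:
        raise ValueError("empty ground truth")
    extra = set(matrix.unit_ids) - set(truth)
    if extra:
        raise ValueError(f"census units missing from truth: {sorted(extra)[:5]}")
    pred: dict[str, str] = {}
    for acc in truth:
        if acc in matrix.unit_ids:
            pred[acc] = predict_class(matrix.presence_set(acc))
        else:
            pred[acc] = UNDETECTED
    classes = list(CLASSES) + [UNDETECTED]
    conf = pd.DataFrame(0, index=list(CLASSES), columns=classes)
    mis: dict[str, list[str]] = {c: [] for c in CLASSES}
    for acc in sorted(truth):
        t = truth[acc].klass
        conf.loc[t, pred[acc]] += 1
        if pred[acc] != t:
            mis[t].append(acc)
    accuracy = {}
    for c in CLASSES:
        n = int(conf.loc[c].sum())
        if n:
            accuracy[c] = float(conf.loc[c, c]) / n
    return RecoveryScore(conf, accuracy, mis)
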