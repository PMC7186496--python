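"""Synthetic factorial expression experiments with planted ground truth.

Two experimental arms are emulated:

* a two-group microarray-style arm (disease vs. control, 5 animals per
  group, ~29k probes) producing log2 intensities, and
* a five-group RNA-seq-style arm (two siRNA treatments x two time points
  plus an untreated control, 5 animals per group, ~25k genes) producing
  negative-binomial counts.

Every dataset comes with a :class:`SyntheticTruth` recording exactly which
genes were planted as differential in which contrast, which pathways were
seeded with differential genes, and which genes form the cross-arm
"biomarker panel" — so every downstream stage of the pipeline has a
recoverable ground truth.

Randomness discipline: one root seed; every distinct quantity (baselines,
noise, planted indices, pathway membership, ...) is drawn from a named
substream derived from the root seed, so adding a new draw never perturbs
existing ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datasets import (
    ExpressionDataset,
    read_annotation_tsv,
    read_expression_tsv,
    read_gmt,
    read_metadata_tsv,
    write_annotation_tsv,
    write_expression_tsv,
    write_gmt,
    write_metadata_tsv,
)

TRUTH_SCHEMA_VERSION = 1

CHIP_GROUPS = ("SAH", "normal-1")
RNASEQ_GROUPS = (
    "SAH-siRNA-LCN2-1d",
    "SAH-siRNA-LCN2-3d",
    "SAH-siRNA-NC-1d",
    "SAH-siRNA-NC-3d",
    "normal-2",
)


class ConfigurationError(ValueError):
    """A SimulationConfig field is out of its documented domain."""


@dataclasses.dataclass
class SimulationConfig:
    """Generating parameters for one experimental arm.

    Parameters
    ----------
    n_genes : int
        Size of the measured gene (or probe-target) universe.
    n_per_group : int
        Animals per experimental group.
    arm : str
        ``"chip"`` (log-intensity dialect) or ``"rnaseq"`` (counts).
    group_labels : tuple of str
        Two labels for the chip arm; five for the rnaseq arm.
    n_de_genes : int
        Genes planted differential in the disease-vs-control contrast.
    log2_effect : float
        Planted |log2 fold change| for ordinary differential genes.
    sigma : float
        Gene-wise Gaussian noise scale in the log2 domain.
    n_pathways, pathway_size : int
        Gene-set collection shape.
    de_enriched_pathways : int
        How many pathways are seeded with planted differential genes
        (half of their members drawn from the differential set).
    biomarker_panel_size : int
        Genes planted differential in *both* arms; the recoverable panel.
    n_strong_de : int
        Differential genes (a superset of the panel) given
        ``strong_log2_effect`` instead of ``log2_effect`` — these are the
        genes a strict fold-change filter is meant to isolate.
    strong_log2_effect, top_log2_effect : float
        Effect sizes for the strong set and for the ``top_subset_size``
        highest-signal panel genes.
    top_subset_size : int
        Panel genes planted with the largest effect in both arms; the
        subset the end-to-end workflow is expected to recover.
    dispersion : float
        Negative-binomial dispersion (rnaseq arm only); gene-level
        variance is ``mu + dispersion * mu**2``.
    n_lcn2_specific : int
        rnaseq arm only: genes responding to the active siRNA itself,
        i.e. differential in treatment-vs-vehicle contrasts.
    panel_universe_size : int or None
        Panel genes are drawn from the first this-many gene ids so that a
        smaller second arm still measures them. ``None`` means the whole
        universe.
    seed : int
        Root seed for all substreams.
    """

    n_genes: int = 2000
    n_per_group: int = 5
    arm: str = "chip"
    group_labels: tuple[str, ...] = CHIP_GROUPS
    n_de_genes: int = 100
    log2_effect: float = 2.0
    sigma: float = 0.25
    n_pathways: int = 20
    pathway_size: int = 40
    de_enriched_pathways: int = 3
    biomarker_panel_size: int = 9
    n_strong_de: int = 0
    strong_log2_effect: float = 2.5
    top_log2_effect: float = 3.5
    top_subset_size: int = 0
    dispersion: float = 0.1
    n_lcn2_specific: int = 0
    panel_universe_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arm not in ("chip", "rnaseq"):
            raise ConfigurationError(f"arm must be 'chip' or 'rnaseq', got {self.arm!r}")
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if self.n_per_group <= 0:
            raise ConfigurationError("n_per_group must be positive")
        if self.n_de_genes < 0 or self.n_de_genes > self.n_genes:
            raise ConfigurationError("n_de_genes must lie in [0, n_genes]")
        if self.biomarker_panel_size > self.n_de_genes:
            raise ConfigurationError("biomarker_panel_size must not exceed n_de_genes")
        if self.pathway_size > self.n_genes:
            raise ConfigurationError("pathway_size must not exceed n_genes")
        if self.n_strong_de and not (
            self.biomarker_panel_size <= self.n_strong_de <= self.n_de_genes
        ):
            raise ConfigurationError(
                "n_strong_de must lie in [biomarker_panel_size, n_de_genes]"
            )
        if self.top_subset_size > self.biomarker_panel_size:
            raise ConfigurationError("top_subset_size must not exceed biomarker_panel_size")
        if self.sigma < 0:
            raise ConfigurationError("sigma must be nonnegative")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")
        if self.panel_universe_size is not None and self.panel_universe_size > self.n_genes:
            raise ConfigurationError("panel_universe_size must not exceed n_genes")


@dataclasses.dataclass
class SyntheticTruth:
    """Planted ground truth attached to a simulated dataset.

    ``de_genes_by_contrast`` maps a contrast name to a mapping of gene id
    -> planted signed log2 effect. ``biomarker_panel`` maps panel gene id
    -> sign. Gene ids (not probe ids) are used throughout; for the chip
    arm the ``annotation`` table translates row (probe) ids to gene ids.
    """

    de_genes_by_contrast: dict[str, dict[str, float]]
    pathway_membership: dict[str, set[str]]
    biomarker_panel: dict[str, int]
    generating_parameters: SimulationConfig
    strong_genes: set[str] = dataclasses.field(default_factory=set)
    top_genes: set[str] = dataclasses.field(default_factory=set)
    annotation: pd.DataFrame | None = None


def _substream(seed: int, name: str) -> np.random.Generator:
    """A reproducible generator keyed by (seed, substream name)."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


def gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def default_chip_config(seed: int = 0) -> SimulationConfig:
    """The chip-arm study conditions: 5 disease vs 5 control animals,
    28,944 probed genes, a moderate differential background plus 47
    strong-effect genes containing a 9-gene cross-arm panel."""
    return SimulationConfig(
        n_genes=28944,
        n_per_group=5,
        arm="chip",
        group_labels=CHIP_GROUPS,
        n_de_genes=2900,
        log2_effect=0.6,
        sigma=0.25,
        n_pathways=50,
        pathway_size=40,
        de_enriched_pathways=3,
        biomarker_panel_size=9,
        n_strong_de=47,
        strong_log2_effect=2.5,
        top_log2_effect=3.5,
        top_subset_size=3,
        panel_universe_size=25000,
        seed=seed,
    )


def default_rnaseq_config(seed: int = 0) -> SimulationConfig:
    """The rnaseq-arm study conditions: five groups of 5 animals
    (active siRNA and vehicle siRNA at day 1 and day 3, plus untreated
    control), ~25,000 genes, overdispersed counts."""
    return SimulationConfig(
        n_genes=25000,
        n_per_group=5,
        arm="rnaseq",
        group_labels=RNASEQ_GROUPS,
        n_de_genes=1500,
        log2_effect=1.2,
        sigma=0.25,
        n_pathways=50,
        pathway_size=40,
        de_enriched_pathways=3,
        biomarker_panel_size=9,
        n_strong_de=0,
        top_subset_size=3,
        dispersion=0.1,
        n_lcn2_specific=60,
        seed=seed,
    )


def _plant_effects(config: SimulationConfig, panel: Mapping[str, int] | None):
    """Choose differential genes, signs and magnitudes.

    Returns (effects: dict gene_id -> signed log2 effect, panel: dict
    gene_id -> sign, strong: set, top: set).
    """
    ids = gene_ids(config.n_genes)
    rng = _substream(config.seed, "plant")
    panel_bound = config.panel_universe_size or config.n_genes

    if panel is None:
        k = config.biomarker_panel_size
        panel_idx = rng.choice(panel_bound, size=k, replace=False)
        panel_signs = rng.choice([-1, 1], size=k)
        panel = {ids[i]: int(s) for i, s in zip(panel_idx, panel_signs)}
    else:
        missing = [g for g in panel if g not in set(ids)]
        if missing:
            raise ConfigurationError(f"panel genes not in gene universe: {missing[:5]}")
        panel = dict(panel)

    # top subset = first genes of the panel in draw order (deterministic)
    panel_list = list(panel)
    top = set(panel_list[: config.top_subset_size])

    pool = [g for g in ids if g not in panel]
    pool = [pool[i] for i in rng.permutation(len(pool))]
    n_strong_extra = max(config.n_strong_de - len(panel), 0)
    strong_extra = pool[:n_strong_extra]
    n_bg = max(config.n_de_genes - len(panel) - len(strong_extra), 0)
    background = pool[n_strong_extra : n_strong_extra + n_bg]

    effects: dict[str, float] = {}
    for g, s in panel.items():
        mag = config.top_log2_effect if g in top else config.strong_log2_effect
        if not config.n_strong_de:
            mag = config.top_log2_effect if g in top else config.log2_effect
        effects[g] = s * mag
    signs = rng.choice([-1, 1], size=len(strong_extra) + len(background))
    for g, s in zip(strong_extra, signs[: len(strong_extra)]):
        effects[g] = int(s) * config.strong_log2_effect
    for g, s in zip(background, signs[len(strong_extra) :]):
        effects[g] = int(s) * config.log2_effect

    strong = set(panel) | set(strong_extra) if config.n_strong_de else set()
    return effects, panel, strong, top


def _make_pathways(config: SimulationConfig, de_genes: list[str]) -> dict[str, set[str]]:
    ids = gene_ids(config.n_genes)
    rng = _substream(config.seed, "pathways")
    pathways: dict[str, set[str]] = {}
    de = list(de_genes)
    for p in range(config.n_pathways):
        name = f"pathway_{p:03d}"
        if p < config.de_enriched_pathways and de:
            n_seed = min(config.pathway_size // 2, len(de))
            seeded = list(rng.choice(de, size=n_seed, replace=False))
            rest = rng.choice(config.n_genes, size=config.pathway_size, replace=False)
            members = set(seeded)
            for i in rest:
                if len(members) >= config.pathway_size:
                    break
                members.add(ids[i])
            pathways[name] = members
        else:
            idx = rng.choice(config.n_genes, size=config.pathway_size, replace=False)
            pathways[name] = {ids[i] for i in idx}
    return pathways


def _metadata(groups: tuple[str, ...], n_per_group: int) -> pd.DataFrame:
    rows = []
    for grp in groups:
        time = "1d" if "1d" in grp else ("3d" if "3d" in grp else "na")
        if "LCN2" in grp:
            treatment = "siRNA-LCN2"
        elif "NC" in grp:
            treatment = "siRNA-NC"
        else:
            treatment = "none"
        for r in range(n_per_group):
            rows.append(
                {
                    "sample_id": f"{grp}_r{r + 1}",
                    "group": grp,
                    "time": time,
                    "treatment": treatment,
                }
            )
    return pd.DataFrame(rows)


def _chip_annotation(config: SimulationConfig, n_duplicate: int = 8) -> pd.DataFrame:
    """Probe -> gene map; the first ``n_duplicate`` genes get a second probe."""
    ids = gene_ids(config.n_genes)
    probes = [f"p_{g}_1" for g in ids]
    genes = list(ids)
    for g in ids[:n_duplicate]:
        probes.append(f"p_{g}_2")
        genes.append(g)
    return pd.DataFrame({"probe_id": probes, "gene_id": genes})


def simulate_chip_arm(
    config: SimulationConfig, panel: Mapping[str, int] | None = None
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Simulate the two-group log-intensity arm.

    Per-probe baseline drawn uniformly on log2 [4, 12]; i.i.d. Gaussian
    noise of scale ``sigma`` in the log2 domain; planted genes shifted by
    their signed effect in the disease group. Rows are probe ids; the
    accompanying annotation table maps them to gene ids (a few genes carry
    two probes, to exercise de-duplication downstream).
    """
    if config.arm != "chip":
        raise ConfigurationError("simulate_chip_arm requires arm='chip'")
    if len(config.group_labels) != 2:
        raise ConfigurationError("chip arm requires exactly two group labels")

    effects, panel_map, strong, top = _plant_effects(config, panel)
    annotation = _chip_annotation(config)
    meta = _metadata(config.group_labels, config.n_per_group)
    disease, control = config.group_labels

    rng_base = _substream(config.seed, "chip-baseline")
    rng_noise = _substream(config.seed, "chip-noise")

    probes = list(annotation["probe_id"])
    probe_gene = list(annotation["gene_id"])
    n_probes = len(probes)
    n_samples = len(meta)
    baseline = rng_base.uniform(4.0, 12.0, size=n_probes)
    noise = rng_noise.normal(0.0, config.sigma, size=(n_probes, n_samples))

    effect_vec = np.array([effects.get(g, 0.0) for g in probe_gene])
    in_disease = (meta["group"] == disease).to_numpy()
    matrix = baseline[:, None] + noise + np.outer(effect_vec, in_disease.astype(float))

    values = pd.DataFrame(matrix, index=probes, columns=list(meta["sample_id"]))
    dataset = ExpressionDataset(values, meta, dialect="log")

    contrast = f"{disease}_vs_{control}"
    truth = SyntheticTruth(
        de_genes_by_contrast={contrast: dict(effects)},
        pathway_membership=_make_pathways(config, sorted(effects)),
        biomarker_panel=panel_map,
        generating_parameters=config,
        strong_genes=strong,
        top_genes=top,
        annotation=annotation,
    )
    return dataset, truth


def simulate_rnaseq_arm(
    config: SimulationConfig, panel: Mapping[str, int] | None = None
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Simulate the five-group count arm.

    Counts follow a log-normal/negative-binomial hierarchy: per-gene
    baseline log2 mean uniform on [3, 10]; disease effect added in every
    disease group; siRNA-specific effect added in the active-siRNA groups
    for ``n_lcn2_specific`` genes; per-observation log-normal jitter of
    scale ``sigma``; counts drawn gamma-Poisson with the configured
    dispersion (variance mu + dispersion*mu^2).
    """
    if config.arm != "rnaseq":
        raise ConfigurationError("simulate_rnaseq_arm requires arm='rnaseq'")
    if len(config.group_labels) != 5:
        raise ConfigurationError("rnaseq arm requires exactly five group labels")

    effects, panel_map, _, top = _plant_effects(config, panel)
    # panel genes keep their chip-style magnitudes; others use log2_effect
    ids = gene_ids(config.n_genes)
    meta = _metadata(config.group_labels, config.n_per_group)
    control = config.group_labels[-1]
    disease_groups = list(config.group_labels[:-1])
    lcn2_groups = [g for g in disease_groups if "LCN2" in g]

    rng_base = _substream(config.seed, "rnaseq-baseline")
    rng_noise = _substream(config.seed, "rnaseq-noise")
    rng_counts = _substream(config.seed, "rnaseq-counts")
    rng_lcn2 = _substream(config.seed, "rnaseq-lcn2")

    # siRNA-specific responders, disjoint from the panel
    pool = [g for g in ids if g not in panel_map]
    lcn2_idx = rng_lcn2.choice(len(pool), size=min(config.n_lcn2_specific, len(pool)), replace=False)
    lcn2_signs = rng_lcn2.choice([-1, 1], size=len(lcn2_idx))
    lcn2_effects = {pool[i]: int(s) * config.log2_effect for i, s in zip(lcn2_idx, lcn2_signs)}

    n_samples = len(meta)
    baseline = rng_base.uniform(3.0, 10.0, size=config.n_genes)
    disease_vec = np.array([effects.get(g, 0.0) for g in ids])
    lcn2_vec = np.array([lcn2_effects.get(g, 0.0) for g in ids])
    in_disease = meta["group"].isin(disease_groups).to_numpy().astype(float)
    in_lcn2 = meta["group"].isin(lcn2_groups).to_numpy().astype(float)

    log2_mu = (
        baseline[:, None]
        + np.outer(disease_vec, in_disease)
        + np.outer(lcn2_vec, in_lcn2)
        + rng_noise.normal(0.0, config.sigma, size=(config.n_genes, n_samples))
    )
    mu = np.exp2(log2_mu)
    shape = 1.0 / config.dispersion
    lam = rng_counts.gamma(shape, mu * config.dispersion)
    counts = rng_counts.poisson(lam).astype(np.int64)

    values = pd.DataFrame(counts, index=ids, columns=list(meta["sample_id"]))
    dataset = ExpressionDataset(values, meta, dialect="counts")

    de_by_contrast: dict[str, dict[str, float]] = {}
    for grp in disease_groups:
        contrast = f"{grp}_vs_{control}"
        planted = dict(effects)
        if grp in lcn2_groups:
            for g, e in lcn2_effects.items():
                planted[g] = planted.get(g, 0.0) + e
        de_by_contrast[contrast] = planted
    for day in ("1d", "3d"):
        lcn2 = next(g for g in lcn2_groups if day in g)
        nc = next(g for g in disease_groups if "NC" in g and day in g)
        de_by_contrast[f"{lcn2}_vs_{nc}"] = dict(lcn2_effects)

    truth = SyntheticTruth(
        de_genes_by_contrast=de_by_contrast,
        pathway_membership=_make_pathways(config, sorted(effects)),
        biomarker_panel=panel_map,
        generating_parameters=config,
        strong_genes=set(),
        top_genes=top,
        annotation=None,
    )
    return dataset, truth


def simulate_classification(
    n_samples: int = 200,
    n_informative: int = 3,
    n_noise: int = 20,
    shift: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-class Gaussian benchmark for the classifier stage.

    Informative features are shifted by ``shift`` (in units of the unit
    noise s.d.) in the positive class; the rest are pure noise. Returns
    ``(X, y)`` with a balanced 0/1 label vector.
    """
    rng = _substream(seed, "classification")
    y = np.zeros(n_samples, dtype=int)
    y[n_samples // 2 :] = 1
    rng.shuffle(y)
    n_features = n_informative + n_noise
    X = rng.normal(0.0, 1.0, size=(n_samples, n_features))
    X[:, :n_informative] += shift * y[:, None]
    return X, y


def simulate_benchmark(
    seed: int = 0,
    n_samples: int = 200,
    n_informative: int = 3,
    n_noise: int = 20,
    shift: float = 0.8,
    disease_scale: float = 1.8,
    rho: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Classifier benchmark emulating a measured gene panel.

    Unlike :func:`simulate_classification`, this generator reproduces two
    features of real expression panels that make the classifier
    comparison non-degenerate: a shared correlated background across all
    genes (equicorrelation ``rho``, emulating sample-level technical
    variation) and an inflated within-class scale for the disease class
    on the informative genes (``disease_scale``, emulating the larger
    biological heterogeneity of disease samples). With spherical
    Gaussian classes every linear learner is near-optimal and the
    ensemble comparison collapses to ties; here the optimal boundary is
    curved and the learners genuinely differ.
    """
    rng = _substream(seed, "benchmark")
    y = np.zeros(n_samples, dtype=int)
    y[n_samples // 2 :] = 1
    perm = rng.permutation(n_samples)
    y = y[perm]
    p = n_informative + n_noise
    shared = rng.normal(size=(n_samples, 1))
    X = np.sqrt(1.0 - rho) * rng.normal(size=(n_samples, p)) + np.sqrt(rho) * shared
    X[:, :n_informative] += shift * y[:, None]
    X[y == 1, :n_informative] *= disease_scale
    return X, y


# ---------------------------------------------------------------------------
# Fixture bundles


def _truth_to_json(truth: SyntheticTruth) -> dict:
    return {
        "schema_version": TRUTH_SCHEMA_VERSION,
        "de_genes_by_contrast": {
            c: {g: float(e) for g, e in sorted(m.items())}
            for c, m in truth.de_genes_by_contrast.items()
        },
        "pathway_membership": {p: sorted(s) for p, s in truth.pathway_membership.items()},
        "biomarker_panel": {g: int(s) for g, s in truth.biomarker_panel.items()},
        "strong_genes": sorted(truth.strong_genes),
        "top_genes": sorted(truth.top_genes),
        "generating_parameters": dataclasses.asdict(truth.generating_parameters),
    }


def _truth_from_json(doc: dict) -> SyntheticTruth:
    params = dict(doc["generating_parameters"])
    params["group_labels"] = tuple(params["group_labels"])
    return SyntheticTruth(
        de_genes_by_contrast={c: dict(m) for c, m in doc["de_genes_by_contrast"].items()},
        pathway_membership={p: set(s) for p, s in doc["pathway_membership"].items()},
        biomarker_panel={g: int(s) for g, s in doc["biomarker_panel"].items()},
        generating_parameters=SimulationConfig(**params),
        strong_genes=set(doc["strong_genes"]),
        top_genes=set(doc["top_genes"]),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_bundle(
    dataset: ExpressionDataset, truth: SyntheticTruth, directory: str | Path
) -> dict:
    """Write the dataset, metadata, gene sets, truth and a manifest.

    Returns the manifest (also written as ``manifest.json``): file names,
    sha256 checksums, the dialect and the generating seed. Round-trips
    losslessly through :func:`read_fixture_bundle`.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise OSError(f"cannot create fixture directory {directory}: {exc}") from exc

    files: dict[str, str] = {}

    def _emit(name: str, writer) -> None:
        path = directory / name
        writer(path)
        files[name] = _sha256(path)

    _emit("expression.tsv", lambda p: write_expression_tsv(dataset, p))
    _emit("metadata.tsv", lambda p: write_metadata_tsv(dataset.metadata, p))
    _emit("pathways.gmt", lambda p: write_gmt(truth.pathway_membership, p))
    _emit(
        "truth.json",
        lambda p: p.write_text(json.dumps(_truth_to_json(truth), indent=1, sort_keys=True)),
    )
    if truth.annotation is not None:
        _emit("annotation.tsv", lambda p: write_annotation_tsv(truth.annotation, p))

    manifest = {
        "files": files,
        "dialect": dataset.dialect,
        "seed": truth.generating_parameters.seed,
        "truth_schema_version": TRUTH_SCHEMA_VERSION,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def read_fixture_bundle(directory: str | Path) -> tuple[ExpressionDataset, SyntheticTruth]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    meta = read_metadata_tsv(directory / "metadata.tsv")
    dataset = read_expression_tsv(directory / "expression.tsv", meta, dialect=manifest["dialect"])
    if dataset.dialect == "counts":
        dataset.values[:] = dataset.values.astype(np.int64)
    truth = _truth_from_json(json.loads((directory / "truth.json").read_text()))
    truth.pathway_membership = read_gmt(directory / "pathways.gmt")
    if (directory / "annotation.tsv").exists():
        truth.annotation = read_annotation_tsv(directory / "annotation.tsv")
    return dataset, truth


def check_truth_consistency(dataset: ExpressionDataset, truth: SyntheticTruth) -> None:
    """Raise AssertionError if planted ids cannot be resolved in the dataset."""
    if truth.annotation is not None:
        measured = set(truth.annotation["gene_id"])
    else:
        measured = set(dataset.gene_ids)
    for contrast, genes in truth.de_genes_by_contrast.items():
        stray = set(genes) - measured
        assert not stray, f"contrast {contrast}: planted genes absent from dataset: {sorted(stray)[:5]}"
    for pathway, members in truth.pathway_membership.items():
        stray = members - measured
        assert not stray, f"pathway {pathway}: members absent from dataset: {sorted(stray)[:5]}"
    assert set(truth.biomarker_panel) <= measured
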