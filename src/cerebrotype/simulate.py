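"""Synthetic data with the statistical structure the analysis assumes.

The generator emits a complete study bundle — an ultrametric phylogeny, 3D
landmark configurations evolved by Brownian motion with locomotor-mode
mean shifts and an allometric size effect, per-mode volume allometries
(optionally with unequal slopes), per-species Purkinje-cell depth
distributions drawn from four scattering archetypes, and an ortholog FPKM
matrix with three expression archetypes plus GO annotations — together
with a ``truth`` record of every generating parameter, so parameter
recovery and calibration of every downstream stage can be tested without
any external data.

Defaults mirror the structure of a 40-species squamate panel with seven
locomotor modes, 61 whole-brain landmarks plus 5 cerebellar interface
landmarks, and a 630-gene one-to-one ortholog matrix.

All randomness flows from a single integer seed; each generator draws from
a deterministically derived sub-stream, so a fixed seed yields
bit-identical bundles regardless of which generators are invoked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cell_scatter import CellDepthTable
from .expression import ExpressionMatrix
from .morphometry import LandmarkSet
from .trees import PhyloTree
from .volumetrics import VolumeTable

__all__ = [
    "MODE_LABELS",
    "DEPTH_ARCHETYPES",
    "SimConfig",
    "SyntheticBundle",
    "simulate_tree",
    "simulate_landmarks",
    "simulate_volumes",
    "simulate_cell_depths",
    "simulate_expression",
    "simulate_bundle",
    "write_bundle",
]

# the seven locomotor categories (anatomy x habitat x movement type)
MODE_LABELS = [
    "limbless_burrower",
    "facultative_burrower",
    "lateral_undulation",
    "multihabitat_other",
    "quadrupedal_arboreal",
    "quadrupedal_terrestrial",
    "quadrupedal_bipedal_aerial",
]

# scattering archetypes as Beta parameters on the 0-100% depth scale:
# (mean %, concentration).  I = ordered monolayer (tight, shallow),
# II = ordered multilayer, III = scattered multilayer, IV = totally
# scattered (mean 50, concentration 2 = the uniform distribution).
# Neighbouring archetypes are kept clearly separated in rank terms
# (pairwise AUC >= ~0.68): the four patterns represent significantly
# different positioning regimes, not a continuum.
DEPTH_ARCHETYPES: dict[str, tuple[float, float]] = {
    "I": (10.0, 60.0),
    "II": (22.0, 25.0),
    "III": (32.0, 7.0),
    "IV": (50.0, 2.0),
}

_MODE_ARCHETYPE = {
    "limbless_burrower": "II",
    "facultative_burrower": "II",
    "lateral_undulation": "III",
    "multihabitat_other": "IV",
    "quadrupedal_arboreal": "I",
    "quadrupedal_terrestrial": "I",
    "quadrupedal_bipedal_aerial": "I",
}

# fixed sub-stream tags so each generator is reproducible in isolation
_STREAMS = {"tree": 1, "landmarks": 2, "volumes": 3, "depths": 4,
            "expression": 5, "modes": 6}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(
        entropy=seed, spawn_key=(_STREAMS[stream],)))


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Generating parameters for a synthetic study bundle.

    Landmark shape model per species: Brownian-motion drift around a fixed
    base shape, plus a fixed per-mode displacement field of per-landmark
    magnitude ``mode_effect``, plus an allometric deformation proportional
    to the species' log-size deviation, plus i.i.d. digitisation noise of
    standard deviation ``noise_sd``.  All four act in the same shape units
    (base coordinates of order 1; the size factor is applied afterwards),
    so effect magnitudes are directly comparable.  Defaults emulate a
    study where phylogeny is the dominant signal and digitisation error is
    small: Brownian tip SD per coordinate 0.05 (sqrt of ``bm_rate`` over
    the depth-1 tree), mode displacement 0.03 per landmark (three times
    the digitisation noise of 0.01), and an allometric effect sized to
    predict roughly a tenth of shape variation.
    """

    n_species: int = 40
    n_landmarks: int = 61          # whole-brain landmarks
    n_extra_cerebellum: int = 5    # interface landmarks, cerebellum set only
    n_cerebellum_whole: int = 16   # whole-brain landmarks also in cerebellum set
    n_modes: int = 7
    replicates: int = 1            # digitisation sessions per specimen

    bm_rate: float = 2.5e-3        # shape BM variance per unit branch length
    mode_effect: float = 0.03      # per-landmark mean displacement magnitude
    allometry_coeff: float = 0.015  # shape change per unit log centroid size
    noise_sd: float = 0.01
    log_size_sd: float = 0.5       # spread of log centroid size across species
    mean_log_size: float = np.log(1000.0)     # µm scale

    volume_slopes: tuple[float, ...] = (1.20, 1.10, 1.05, 1.00, 0.95, 0.90, 0.85)
    volume_intercepts: tuple[float, ...] = (-3.2, -2.6, -2.6, -2.6, -2.4,
                                            -2.4, -2.4)
    volume_bm_sd: float = 0.12     # residual SD on the log scale
    volume_lambda: float = 0.0     # phylogenetic share of the volume error
    log_brain_range: tuple[float, float] = (0.5, 4.5)   # ln mm^3

    depth_archetypes: dict[str, tuple[float, float]] | None = None
    cells_per_species: tuple[int, int] = (250, 750)
    ml_thickness_um: float = 120.0

    n_genes: int = 630
    cluster_props: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    expr_mode_sd: float = 1.0      # archetype-3 per-mode shift SD (log scale)
    expr_noise_sd: float = 0.3     # residual log-normal noise
    n_go_terms: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.n_landmarks < 2 or self.n_modes < 2:
            raise ValueError("counts must be >= 2")
        if abs(sum(self.cluster_props) - 1.0) > 1e-9:
            raise ValueError("cluster_props must sum to 1")
        if any(p < 0 for p in self.cluster_props):
            raise ValueError("cluster_props must be non-negative")
        if len(self.volume_slopes) < self.n_modes:
            raise ValueError("volume_slopes needs one entry per mode")
        if self.depth_archetypes is None:
            self.depth_archetypes = {
                m: DEPTH_ARCHETYPES[_MODE_ARCHETYPE[m]]
                for m in self.mode_labels()}
        for m, (mu, _) in self.depth_archetypes.items():
            if not 0 < mu < 100:
                raise ValueError(
                    f"depth archetype mean for {m!r} outside (0, 100)")
        if self.n_genes < self.n_go_terms:
            raise ValueError("n_genes must be >= n_go_terms")

    def mode_labels(self) -> list[str]:
        if self.n_modes <= len(MODE_LABELS):
            return MODE_LABELS[:self.n_modes]
        return MODE_LABELS + [f"mode{i}" for i in
                              range(len(MODE_LABELS), self.n_modes)]


@dataclass
class SyntheticBundle:
    """A complete synthetic study with its generating parameters."""

    tree: PhyloTree
    landmarks: LandmarkSet
    sessions: list[LandmarkSet]
    modes: dict[str, str]
    volumes: VolumeTable
    depths: CellDepthTable
    expression: ExpressionMatrix
    go: pd.DataFrame
    truth: dict = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        return self.tree.tip_labels


# --------------------------------------------------------------------------
# tree
# --------------------------------------------------------------------------

def simulate_tree(n_species: int, seed: int) -> PhyloTree:
    """Pure-birth (Yule) ultrametric tree, total depth scaled to 1.

    Lineages split at unit rate, a uniformly chosen lineage splitting at
    each event; the final inter-event draw extends the present so terminal
    branches are strictly positive.  Tips are labelled sp01, sp02, ... in
    birth order.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = _rng(seed, "tree")

    children: dict[int, list[int]] = {0: []}
    birth = {0: 0.0}
    active = [0]
    t = 0.0
    nxt = 1
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        parent = active.pop(rng.integers(len(active)))
        for _ in range(2):
            children[nxt] = []
            birth[nxt] = t
            children[parent].append(nxt)
            active.append(nxt)
            nxt += 1
    present = t + rng.exponential(1.0 / n_species)

    tips = sorted(active)
    label = {node: f"sp{k + 1:02d}" for k, node in enumerate(tips)}
    # the root's own stem is dropped, so depth runs from the first split
    depth = present - birth[children[0][0]]

    def newick(node: int, parent_birth: float) -> str:
        length = ((present if not children[node] else
                   birth[children[node][0]]) - parent_birth) / depth
        if not children[node]:
            return f"{label[node]}:{length:.10f}"
        inner = ",".join(newick(c, birth[c]) for c in children[node])
        return f"({inner}):{length:.10f}"

    if children[0]:
        inner = ",".join(newick(c, birth[c]) for c in children[0])
        nwk = f"({inner});"
    else:  # n_species == 1 cannot happen (guarded above)
        nwk = f"({label[0]}:1);"
    return PhyloTree.from_newick(nwk)


def _bm_tips(tree: PhyloTree, species: list[str], rate: float, p: int,
             rng: np.random.Generator) -> np.ndarray:
    """Tip values of p independent BM traits (zero root state)."""
    C = tree.covariance(species)
    L = np.linalg.cholesky(C)
    return np.sqrt(rate) * (L @ rng.standard_normal((len(species), p)))


def assign_modes(tree: PhyloTree, config: SimConfig) -> dict[str, str]:
    """Round-robin assignment of modes over a random species order.

    Shuffling before the round-robin decouples mode membership from the
    tip ordering of the tree while keeping group sizes balanced.
    """
    rng = _rng(config.seed, "modes")
    species = list(tree.tip_labels)
    rng.shuffle(species)
    labels = config.mode_labels()
    return {sp: labels[i % len(labels)] for i, sp in enumerate(species)}


# --------------------------------------------------------------------------
# landmarks
# --------------------------------------------------------------------------

def simulate_landmarks(tree: PhyloTree, modes: dict[str, str],
                       config: SimConfig) -> list[LandmarkSet]:
    """Landmark digitisation sessions for every species.

    Per species: base shape + BM drift + mode displacement field +
    allometric deformation x (log size deviation), all scaled by the
    species' size factor, plus i.i.d. session noise.  Returns one
    LandmarkSet per digitisation session (``config.replicates`` of them);
    average them with :func:`~cerebrotype.morphometry.average_replicates`
    before analysis, as one would with real digitisation replicates.
    """
    species = list(tree.tip_labels)
    missing = [s for s in species if s not in modes]
    if missing:
        raise KeyError(f"mode map missing species: {missing}")
    rng = _rng(config.seed, "landmarks")
    k = config.n_landmarks + config.n_extra_cerebellum
    p = 3 * k

    base = rng.uniform(-1.0, 1.0, size=(k, 3))
    mode_fields = {}
    for m in config.mode_labels():
        d = rng.standard_normal((k, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        mode_fields[m] = d * config.mode_effect
    allo = rng.standard_normal((k, 3))
    allo /= np.linalg.norm(allo, axis=1, keepdims=True)

    drift = _bm_tips(tree, species, config.bm_rate, p, rng)
    log_size = config.mean_log_size + config.log_size_sd * \
        rng.standard_normal(len(species))
    size_dev = log_size - log_size.mean()

    shapes = np.empty((len(species), k, 3))
    scale = np.empty(len(species))
    for i, sp in enumerate(species):
        shapes[i] = (base + drift[i].reshape(k, 3) + mode_fields[modes[sp]]
                     + config.allometry_coeff * size_dev[i] * allo)
        # unit-magnitude shape units to a µm-scale organ size
        scale[i] = 250.0 * np.exp(log_size[i] - config.mean_log_size)

    n_cb = config.n_cerebellum_whole
    subsets = {
        "whole_brain": np.arange(config.n_landmarks),
        "cerebellum": np.arange(config.n_landmarks - n_cb, k),
    }
    sessions = []
    for _ in range(max(config.replicates, 1)):
        # digitisation noise acts in shape units, before the size factor,
        # so mode_effect and noise_sd are directly comparable magnitudes
        noisy = (shapes + config.noise_sd
                 * rng.standard_normal(shapes.shape)) * scale[:, None, None]
        sessions.append(LandmarkSet(noisy, list(species), list(species),
                                    {k_: v.copy() for k_, v in subsets.items()}))
    return sessions


# --------------------------------------------------------------------------
# volumes
# --------------------------------------------------------------------------

def simulate_volumes(tree: PhyloTree, modes: dict[str, str],
                     config: SimConfig) -> VolumeTable:
    """Per-mode log-log volume allometries.

    log(cerebellum) = intercept[mode] + slope[mode] * log(brain) + error,
    where the error mixes a Brownian (tree-correlated) and an independent
    component in the ratio set by ``volume_lambda``.  The default of
    lambda = 0 emulates volumetric residuals with negligible phylogenetic
    signal — the regime in which heterogeneous slopes route the analysis
    into the Johnson–Neyman branch; the default unequal slopes cross
    inside the observed brain-size range so that branch has work to do.
    """
    species = list(tree.tip_labels)
    labels = config.mode_labels()
    if len(config.volume_slopes) < len(labels):
        raise ValueError("volume_slopes needs one entry per mode")
    if not 0.0 <= config.volume_lambda <= 1.0:
        raise ValueError("volume_lambda must lie in [0, 1]")
    rng = _rng(config.seed, "volumes")
    slopes = {m: config.volume_slopes[i] for i, m in enumerate(labels)}
    intercepts = {m: config.volume_intercepts[i] for i, m in enumerate(labels)}
    lo, hi = config.log_brain_range
    log_brain = rng.uniform(lo, hi, size=len(species))
    lam = config.volume_lambda
    err = (np.sqrt(lam)
           * _bm_tips(tree, species, config.volume_bm_sd ** 2, 1, rng).ravel()
           + np.sqrt(1.0 - lam) * config.volume_bm_sd
           * rng.standard_normal(len(species)))
    log_cb = np.array([
        intercepts[modes[s]] + slopes[modes[s]] * log_brain[i] + err[i]
        for i, s in enumerate(species)])
    over = log_cb >= log_brain
    if over.any():
        # keep the table valid: a cerebellum is never the whole brain
        log_cb[over] = log_brain[over] - 0.05
    return VolumeTable(species, np.exp(log_brain), np.exp(log_cb),
                       [modes[s] for s in species])


# --------------------------------------------------------------------------
# cell depths
# --------------------------------------------------------------------------

def simulate_cell_depths(modes: dict[str, str],
                         config: SimConfig) -> CellDepthTable:
    """Per-species Purkinje-cell depth samples from the mode's archetype.

    Depth percentages are Beta-distributed with the archetype's mean and
    concentration (monolayer: shallow and tight; totally scattered:
    uniform); each draw is stored as a raw (distance, thickness) pair
    whose ratio reproduces the percentage, with per-cell ML thickness
    log-normally dispersed around ``ml_thickness_um``.
    """
    rng = _rng(config.seed, "depths")
    species, cell_ids, dists, thicks = [], [], [], []
    lo, hi = config.cells_per_species
    for sp in sorted(modes):
        mu, kappa = config.depth_archetypes[modes[sp]]
        if not 0 < mu < 100:
            raise ValueError(f"archetype mean for {sp!r} outside (0, 100)")
        a = mu / 100.0 * kappa
        b = (1 - mu / 100.0) * kappa
        n = int(rng.integers(lo, hi + 1))
        pct = rng.beta(a, b, size=n)
        thick = config.ml_thickness_um * np.exp(0.2 * rng.standard_normal(n))
        species.extend([sp] * n)
        cell_ids.extend(f"{sp}_c{j}" for j in range(n))
        dists.append(pct * thick)
        thicks.append(thick)
    return CellDepthTable(species, cell_ids, np.concatenate(dists),
                          np.concatenate(thicks))


# --------------------------------------------------------------------------
# expression
# --------------------------------------------------------------------------

def simulate_expression(modes: dict[str, str], config: SimConfig
                        ) -> tuple[ExpressionMatrix, pd.DataFrame, np.ndarray]:
    """FPKM matrix with three gene archetypes and GO annotations.

    Archetype 1: high expression in all species; archetype 2: low in all;
    archetype 3: per-mode mean shifts shared by species of the same mode,
    which is what lets the species dendrogram group by locomotor mode
    rather than phylogeny.  Values are log-normal around the archetype
    mean.  One GO term ("locomotory behaviour") is preferentially assigned
    to archetype-3 genes so the enrichment stage has a planted positive.
    Returns (matrix, annotation table, per-gene archetype array).
    """
    rng = _rng(config.seed, "expression")
    species = sorted(modes)
    n, g = len(species), config.n_genes
    props = np.asarray(config.cluster_props)
    counts = np.floor(props * g).astype(int)
    counts[0] += g - counts.sum()
    archetype = np.repeat([1, 2, 3], counts)

    base_mu = {1: np.log(50.0), 2: np.log(1.5), 3: np.log(8.0)}
    mode_list = config.mode_labels()
    logv = np.empty((g, n))
    for gi in range(g):
        mu = base_mu[archetype[gi]] + 0.4 * rng.standard_normal()
        shift = {m: 0.0 for m in mode_list}
        if archetype[gi] == 3:
            # differential genes vary around their own mean level, so the
            # per-mode shifts are centred: the archetype is a pattern
            # across modes, not a change of overall abundance
            raw = config.expr_mode_sd * rng.standard_normal(len(mode_list))
            raw -= raw.mean()
            shift = dict(zip(mode_list, raw))
        for si, sp in enumerate(species):
            logv[gi, si] = (mu + shift[modes[sp]]
                            + config.expr_noise_sd * rng.standard_normal())
    genes = [f"gene{gi + 1:04d}" for gi in range(g)]
    matrix = ExpressionMatrix(
        pd.DataFrame(np.exp(logv), index=genes, columns=species),
        {sp: modes[sp] for sp in species})

    terms = [("GO:0007626", "locomotory behaviour")] + [
        (f"GO:{7000000 + i:07d}", f"process {i}")
        for i in range(1, config.n_go_terms)]
    rows = []
    for gi, gene in enumerate(genes):
        if archetype[gi] == 3:
            if rng.random() < 0.6:
                rows.append((gene, *terms[0]))
        elif rng.random() < 0.05:
            rows.append((gene, *terms[0]))
        for go_id, name in terms[1:]:
            if rng.random() < 0.1:
                rows.append((gene, go_id, name))
    go = pd.DataFrame(rows, columns=["gene", "go_id", "term"])
    return matrix, go, archetype


# --------------------------------------------------------------------------
# bundle
# --------------------------------------------------------------------------

def simulate_bundle(config: SimConfig | None = None, **kwargs) -> SyntheticBundle:
    """Generate the full synthetic study from one configuration."""
    if config is None:
        config = SimConfig(**kwargs)
    tree = simulate_tree(config.n_species, config.seed)
    modes = assign_modes(tree, config)
    sessions = simulate_landmarks(tree, modes, config)
    from .morphometry import average_replicates
    landmarks = (average_replicates(sessions) if len(sessions) > 1
                 else sessions[0])
    volumes = simulate_volumes(tree, modes, config)
    depths = simulate_cell_depths(modes, config)
    expression, go, archetype = simulate_expression(modes, config)
    truth = {
        "config": config,
        "modes": modes,
        "gene_archetypes": dict(zip(expression.genes, archetype.tolist())),
        "depth_archetypes": {sp: config.depth_archetypes[modes[sp]]
                             for sp in modes},
        "volume_slopes": {m: config.volume_slopes[i]
                          for i, m in enumerate(config.mode_labels())},
        "mode_effect": config.mode_effect,
        "noise_sd": config.noise_sd,
        "bm_rate": config.bm_rate,
    }
    return SyntheticBundle(tree, landmarks, sessions, modes, volumes,
                           depths, expression, go, truth)


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write every table of the bundle in its plain-text exchange format."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": out / "tree.nwk",
        "landmarks": out / "landmarks.csv",
        "modes": out / "modes.csv",
        "volumes": out / "volumes.csv",
        "depths": out / "depths.csv",
        "expression": out / "expression.tsv",
        "go": out / "go.tsv",
    }
    bundle.tree.write(str(paths["tree"]))

    lm = bundle.landmarks
    rows = []
    for i, (spec, sp) in enumerate(zip(lm.specimens, lm.species)):
        for j in range(lm.n_landmarks):
            x, y, z = lm.coords[i, j]
            rows.append((spec, sp, j, x, y, z))
    pd.DataFrame(rows, columns=["specimen", "species", "landmark_id",
                                "x", "y", "z"]).to_csv(
        paths["landmarks"], index=False)

    pd.DataFrame(sorted(bundle.modes.items()),
                 columns=["species", "mode"]).to_csv(paths["modes"],
                                                     index=False)
    bundle.volumes.to_dataframe().to_csv(paths["volumes"], index=False)
    bundle.depths.to_dataframe().to_csv(paths["depths"], index=False)
    bundle.expression.to_tsv(str(paths["expression"]))
    bundle.go.to_csv(paths["go"], sep="\t", index=False)
    return paths
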