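"""Synthetic claw data with known ground truth.

Claw outlines are built from two internally tangent circles that meet at
the articulation point P: the sheath dorsal surface is an arc of the outer
circle and the bony-core dorsal surface an arc of the inner circle.  Both
dorsal lips sit a fixed angular offset past P, so the seven-point
measurement protocol recovers the generating arc angles exactly, and the
inner radius is calibrated so the articulation-to-tip arc-length ratio
equals the requested core/sheath length ratio exactly.  Ventral surfaces
are the dorsal arcs offset inward by a tapering width, meeting the dorsal
arcs at the tips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .arcs import ArcMeasurement
from .data import (
    CURVE_SIZES,
    ClawConfiguration,
    Ecology,
    MetadataTable,
    Phylogeny,
    read_newick,
)
from .errors import ValidationError
from .phylo import PhyloCovariance, _lambda_C

import pandas as pd

#: angular offset (degrees) of the dorsal lips past the articulation point
ARTICULATION_OFFSET_DEG = 10.0


@dataclass(frozen=True)
class ClawParams:
    theta_sheath: float = 105.0   # degrees, dorsal sheath arc
    theta_core: float = 76.0      # degrees, dorsal core arc
    length_ratio: float = 0.699   # core/sheath articulation-to-tip arc ratio
    radius: float = 10.0          # sheath circle radius
    base_width: float = 2.0       # proximal claw depth
    taper: float = 1.5            # thickness decay exponent (>= 1)
    noise_sd: float = 0.0         # per-landmark isotropic noise

    def __post_init__(self):
        if not (10.0 <= self.theta_sheath <= 350.0 and 10.0 <= self.theta_core <= 350.0):
            raise ValidationError("arc angles must lie in [10, 350] degrees")
        if not 0.3 <= self.length_ratio <= 1.1:
            raise ValidationError("length_ratio must lie in [0.3, 1.1]")
        if self.radius <= 0 or self.base_width <= 0:
            raise ValidationError("radius and base_width must be positive")
        if self.taper < 1:
            raise ValidationError("taper must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")


def _core_radius(params: ClawParams) -> float:
    delta = ARTICULATION_OFFSET_DEG
    return (
        params.length_ratio
        * params.radius
        * (params.theta_sheath + delta)
        / (params.theta_core + delta)
    )


def _arc_points(center: np.ndarray, radius: float, angles_deg: np.ndarray) -> np.ndarray:
    a = np.radians(angles_deg)
    return center + radius * np.column_stack([np.cos(a), np.sin(a)])


def make_claw(
    params: ClawParams, seed: int, spiral: bool = False
) -> tuple[ClawConfiguration, ArcMeasurement]:
    """Generate one claw configuration plus its exact pre-noise measurement.

    ``spiral=True`` warps the dorsal surfaces into logarithmic spirals (the
    radius grows exponentially along the arc), probing the protocol's
    inscribed-circle assumption; ground truth then still reports the
    nominal circular-arc values.
    """
    delta = ARTICULATION_OFFSET_DEG
    R_s = params.radius
    R_c = _core_radius(params)
    if R_c >= R_s:
        raise ValidationError(
            "core circle would not nest inside the sheath circle; "
            "reduce length_ratio or theta_sheath/theta_core disparity"
        )
    if params.base_width >= 0.9 * R_c:
        raise ValidationError("ventral offset (base_width) exceeds core radius")

    rng = np.random.default_rng(seed)
    phi_p = 90.0  # angle of the articulation point on both circles

    O_s = np.zeros(2)
    P = _arc_points(O_s, R_s, np.array([phi_p]))[0]
    O_c = P - R_c * np.array([math.cos(math.radians(phi_p)), math.sin(math.radians(phi_p))])

    def spiral_radius(base, frac):
        return base * np.exp(0.08 * frac) if spiral else base

    def dorsal(center, base_r, theta, fracs):
        angles = phi_p + delta + fracs * theta
        if spiral:
            pts = [
                _arc_points(center, spiral_radius(base_r, f), np.array([a]))[0]
                for f, a in zip(fracs, angles)
            ]
            return np.array(pts)
        return _arc_points(center, base_r, angles)

    def ventral(center, base_r, theta, width, fracs):
        angles = phi_p + delta + fracs * theta
        radii = spiral_radius(base_r, fracs) - width * (1.0 - fracs) ** params.taper
        a = np.radians(angles)
        return center + radii[:, None] * np.column_stack([np.cos(a), np.sin(a)])

    w_core = 0.5 * params.base_width
    w_sheath = params.base_width

    # fixed landmarks
    lm1 = dorsal(O_c, R_c, params.theta_core, np.array([0.0]))[0]
    lm2 = 2.0 * P - lm1  # articulation midpoint is exactly P
    lm3 = ventral(O_c, R_c, params.theta_core, w_core, np.array([0.0]))[0]
    lm4 = dorsal(O_c, R_c, params.theta_core, np.array([1.0]))[0]
    lm5 = ventral(O_s, R_s, params.theta_sheath, w_sheath, np.array([0.0]))[0]
    lm6 = dorsal(O_s, R_s, params.theta_sheath, np.array([1.0]))[0]

    # semilandmark curves (canonical order SL1, SL2, SL3, SL4)
    k1 = CURVE_SIZES["SL1"]
    sl1 = dorsal(O_c, R_c, params.theta_core, np.arange(1, k1 + 1) / (k1 + 1))
    k2 = CURVE_SIZES["SL2"]
    sl2 = ventral(O_c, R_c, params.theta_core, w_core, np.arange(1, k2 + 1) / (k2 + 1))
    k3 = CURVE_SIZES["SL3"]
    # first SL3 point is the sheath dorsal lip (arc fraction 0); the rest
    # advance toward the tip in steps of 1/k3 so the middle-by-index point
    # sits at the exact angular midpoint
    sl3 = dorsal(O_s, R_s, params.theta_sheath, np.arange(0, k3) / k3)
    k4 = CURVE_SIZES["SL4"]
    sl4 = ventral(O_s, R_s, params.theta_sheath, w_sheath, np.arange(1, k4 + 1) / (k4 + 1))

    coords = np.vstack([[lm1, lm2, lm3, lm4, lm5, lm6], sl1, sl2, sl3, sl4])

    if params.noise_sd > 0:
        coords = coords + rng.normal(0.0, params.noise_sd, size=coords.shape)

    # random rigid motion + modest scale
    angle = rng.uniform(0, 2 * math.pi)
    Rm = np.array(
        [[math.cos(angle), -math.sin(angle)], [math.sin(angle), math.cos(angle)]]
    )
    scale = rng.uniform(0.9, 1.1)
    shift = rng.uniform(-5 * R_s, 5 * R_s, size=2)
    coords = scale * coords @ Rm.T + shift

    core_len = R_c * math.radians(params.theta_core + delta)
    sheath_len = R_s * math.radians(params.theta_sheath + delta)
    truth = ArcMeasurement(
        core_arc_deg=params.theta_core,
        sheath_arc_deg=params.theta_sheath,
        core_length=core_len,
        sheath_length=sheath_len,
        length_ratio=core_len / sheath_len,
    )
    config = ClawConfiguration(specimen_id=f"claw_seed{seed}", coords=coords)
    return config, truth


# ---------------------------------------------------------------------------
# Tree and trait simulation
# ---------------------------------------------------------------------------

def simulate_tree(n_tips: int, seed: int) -> Phylogeny:
    """Pure-birth (Yule) tree rescaled to unit root-to-tip depth."""
    if n_tips < 2:
        raise ValidationError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    # each active lineage: (label, birth_time); splits occur at rate k
    next_id = [0]

    class _Node:
        __slots__ = ("children", "birth", "end", "label")

        def __init__(self, birth):
            self.children = []
            self.birth = birth
            self.end = None
            self.label = None

    t = 0.0
    root = _Node(0.0)
    active = [root]
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / k)
        node = active.pop(rng.integers(k))
        node.end = t
        for _ in range(2):
            child = _Node(t)
            node.children.append(child)
            active.append(child)
    t_final = t + rng.exponential(1.0 / n_tips)
    for i, node in enumerate(active):
        node.end = t_final
        node.label = f"sp{i + 1:03d}"

    def newick(node):
        length = (node.end - node.birth) / t_final if t_final > 0 else 0.0
        if node.children:
            inner = ",".join(newick(c) for c in node.children)
            return f"({inner}):{length:.12f}"
        return f"{node.label}:{length:.12f}"

    return read_newick(newick(root) + ";")


def simulate_bm_traits(
    tree: Phylogeny | PhyloCovariance,
    mean: np.ndarray,
    Sigma: np.ndarray,
    lambda_true: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Matrix-normal tips: row covariance = lambda-transformed phylogenetic
    covariance, column covariance = Sigma."""
    if isinstance(tree, PhyloCovariance):
        cov = tree
    else:
        C, order = tree.covariance()
        cov = PhyloCovariance(species=order, C=C)
    mean = np.atleast_1d(np.asarray(mean, float))
    Sigma = np.atleast_2d(np.asarray(Sigma, float))
    p = len(mean)
    if Sigma.shape != (p, p):
        raise ValidationError("Sigma shape must match mean length")
    evals, evecs = np.linalg.eigh(Sigma)
    if evals.min() < -1e-9 * max(np.trace(Sigma), 1.0):
        raise ValidationError("Sigma is not positive semi-definite")
    Ls = evecs @ np.diag(np.sqrt(np.clip(evals, 0, None)))
    Clam = _lambda_C(cov.C, lambda_true)
    n = cov.n
    ce, cv = np.linalg.eigh(Clam)
    Lc = cv @ np.diag(np.sqrt(np.clip(ce, 0, None)))
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, p))
    tips = mean + Lc @ Z @ Ls.T
    return pd.DataFrame(tips, index=cov.species)


# ---------------------------------------------------------------------------
# Full dataset scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    n_species: int = 30
    specimens_per_species: int = 4
    tree_seed: int = 0
    lambda_true: float = 0.7
    group_rule: str = "random"            # 'random' or 'clade'
    group_fractions: tuple = (0.5, 0.25, 0.25)   # flying, ground, predatory
    # additive offsets on (theta_sheath, theta_core, length_ratio) per group
    group_offsets: dict = field(
        default_factory=lambda: {
            "flying": (0.0, 0.0, 0.0),
            "ground": (-30.0, -21.0, 0.04),
            "predatory": (45.0, 32.0, -0.02),
        }
    )
    base_theta_sheath: float = 105.0
    base_theta_core: float = 76.0
    base_length_ratio: float = 0.699
    # BM rates for (theta_sheath, theta_core, length_ratio, log_size);
    # theta traits co-evolve with correlation 0.9 (integrated by default)
    bm_sd: tuple = (8.0, 6.0, 0.02, 0.5)
    theta_correlation: float = 0.9
    allometry_coef: float = 2.0           # degrees of sheath arc per log size
    within_species_sd: tuple = (5.0, 3.5, 0.012, 0.08)
    noise_sd: float = 0.03                # landmark noise, claw units
    rho_block: float = 0.9                # kept for scenario bookkeeping

    def __post_init__(self):
        if self.n_species < 4:
            raise ValidationError("need at least 4 species")
        if self.specimens_per_species < 1:
            raise ValidationError("need at least 1 specimen per species")
        if not 0.0 <= self.rho_block <= 1.0:
            raise ValidationError("rho_block must be in [0, 1]")
        if self.group_rule not in ("random", "clade"):
            raise ValidationError("group_rule must be 'random' or 'clade'")


def _assign_groups(tree: Phylogeny, scenario: Scenario, rng) -> dict[str, str]:
    tips = list(tree.tips)
    n = len(tips)
    counts = [int(round(f * n)) for f in scenario.group_fractions]
    counts[0] = n - sum(counts[1:])
    names = ["flying", "ground", "predatory"]
    if scenario.group_rule == "random":
        order = list(rng.permutation(tips))
    else:
        # clade-biased: walk a ladder of subtrees so predatory/ground tips
        # cluster phylogenetically (mimics a raptor-heavy clade)
        order = [leaf.taxon.label for leaf in tree.tree.leaf_node_iter()]
    groups: dict[str, str] = {}
    pos = 0
    for name, cnt in zip(names, counts):
        for tip in order[pos:pos + cnt]:
            groups[tip] = name
        pos += cnt
    return groups


@dataclass
class DatasetTruth:
    scenario: Scenario
    seed: int
    species_params: pd.DataFrame       # per-species latent traits (post offsets)
    specimen_params: pd.DataFrame      # per-specimen realized parameters
    groups: dict[str, str]
    arc_truth: dict[str, ArcMeasurement]

    def to_dict(self) -> dict:
        return {
            "scenario": asdict(self.scenario),
            "seed": self.seed,
            "species_params": self.species_params.to_dict(orient="index"),
            "specimen_params": self.specimen_params.to_dict(orient="index"),
            "groups": self.groups,
            "arc_truth": {k: asdict(v) for k, v in self.arc_truth.items()},
        }


def simulate_dataset(
    scenario: Scenario, seed: int
) -> tuple[list[ClawConfiguration], MetadataTable, Phylogeny, DatasetTruth]:
    """Simulate a full study: tree, BM species parameters with ecological
    offsets and weak allometry, per-specimen noise, and claw configurations."""
    rng = np.random.default_rng(seed)
    tree = simulate_tree(scenario.n_species, scenario.tree_seed)
    groups = _assign_groups(tree, scenario, rng)

    mean = np.array(
        [
            scenario.base_theta_sheath,
            scenario.base_theta_core,
            scenario.base_length_ratio,
            0.0,
        ]
    )
    sd = np.asarray(scenario.bm_sd, float)
    Sigma = np.diag(sd**2)
    rho = scenario.theta_correlation
    Sigma[0, 1] = Sigma[1, 0] = rho * sd[0] * sd[1]
    traits = simulate_bm_traits(
        tree, mean, Sigma, scenario.lambda_true, seed=int(rng.integers(2**31))
    )
    traits.columns = ["theta_sheath", "theta_core", "length_ratio", "log_size"]

    for sp in traits.index:
        off = scenario.group_offsets[groups[sp]]
        traits.loc[sp, "theta_sheath"] += off[0]
        traits.loc[sp, "theta_core"] += off[1]
        traits.loc[sp, "length_ratio"] += off[2]
    # weak allometry: larger species get slightly larger sheath arcs
    ls = traits["log_size"] - traits["log_size"].mean()
    traits["theta_sheath"] += scenario.allometry_coef * ls
    traits["theta_core"] += 0.7 * scenario.allometry_coef * ls

    configs: list[ClawConfiguration] = []
    rows = []
    spec_rows = {}
    arc_truth = {}
    wsd = np.asarray(scenario.within_species_sd, float)
    for sp in traits.index:
        for j in range(scenario.specimens_per_species):
            spec_id = f"{sp}_ind{j + 1:02d}"
            jitter = rng.normal(0.0, wsd)
            th_s = float(np.clip(traits.loc[sp, "theta_sheath"] + jitter[0], 15, 340))
            th_c = float(np.clip(traits.loc[sp, "theta_core"] + jitter[1], 12, 330))
            th_c = min(th_c, th_s - 2.0)  # core arc stays flatter than sheath
            lr = float(np.clip(traits.loc[sp, "length_ratio"] + jitter[2], 0.35, 1.05))
            # keep the core circle strictly nested inside the sheath circle
            delta = ARTICULATION_OFFSET_DEG
            lr = min(lr, 0.97 * (th_c + delta) / (th_s + delta))
            logsize = float(traits.loc[sp, "log_size"] + jitter[3])
            radius = 10.0 * math.exp(logsize)
            params = ClawParams(
                theta_sheath=th_s,
                theta_core=th_c,
                length_ratio=lr,
                radius=radius,
                base_width=0.2 * radius,
                taper=1.5,
                noise_sd=scenario.noise_sd * radius,
            )
            cfg, truth = make_claw(params, seed=int(rng.integers(2**31)))
            cfg = ClawConfiguration(
                specimen_id=spec_id,
                coords=cfg.coords,
                species=sp,
                ecology=Ecology(groups[sp]),
            )
            configs.append(cfg)
            arc_truth[spec_id] = truth
            rows.append(
                {"specimen_id": spec_id, "species": sp, "ecology": groups[sp]}
            )
            spec_rows[spec_id] = {
                "theta_sheath": th_s,
                "theta_core": th_c,
                "length_ratio": lr,
                "log_size": logsize,
                "radius": radius,
            }
    metadata = MetadataTable(pd.DataFrame(rows))
    truth = DatasetTruth(
        scenario=scenario,
        seed=seed,
        species_params=traits,
        specimen_params=pd.DataFrame.from_dict(spec_rows, orient="index"),
        groups=groups,
        arc_truth=arc_truth,
    )
    return configs, metadata, tree, truth
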