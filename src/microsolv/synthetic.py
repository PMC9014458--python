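"""Synthetic conformational sampler with known ground truth.

Stand-in for the molecular-dynamics and quantum-chemistry engines: a
rigid toy dianion with two unit-negative binding sites (a
phosphate-like oxygen and a deprotonated-amine-like nitrogen) is
solvated by rigid point-charge waters and sampled with Metropolis
Monte Carlo at a fixed temperature.  A linear observable model then
assigns each conformer a vertical detachment energy (VDE) from its
hydration-site occupancies, so the full downstream pipeline
(clustering -> weighting -> averaging -> site analysis) can be tested
against analytically known answers.

Energy model: intermolecular Coulomb (332.0637 q_i q_j / r) plus a
single Lennard-Jones term 4*eps*((sigma/r)^12 - (sigma/r)^6) between
heavy-atom pairs.  Hydrogens carry charge but no LJ site — the rigid
water geometry keeps them from collapsing onto a charged site, and a
donated hydrogen can then approach an acceptor to ordinary
hydrogen-bond distances.  Waters are rigid (O-H 0.9572 A, H-O-H
104.52 deg); the solute never moves.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .constants import COULOMB_KCAL, R_KCAL
from .structures import AMINE_N10, OTHER, PHOSPHATE_O, Atom, Conformer, Ensemble

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


@dataclass
class ToyModelParams:
    """Parameters of the toy dianion / rigid-water sampler.

    solute_sites: (position A, partial charge e, site_tag) triples; by
    default two unit-negative sites ``site_separation`` apart on the x
    axis plus two neutral carbon "ring" atoms placed symmetrically, so
    the configuration space is symmetric under point inversion through
    the midpoint.
    """

    site_separation: float = 8.0
    solute_sites: list[tuple] | None = None
    water_charges: tuple[float, float] = (-0.834, 0.417)
    lj_sigma: float = 3.15
    lj_epsilon: float = 0.155
    temperature: float = 298.15
    n_waters: int = 1
    mc_steps: int = 5000
    max_translation: float = 0.35
    max_rotation: float = 40.0
    swap_probability: float = 0.15
    teleport_probability: float = 0.05
    container_radius: float = 10.0
    stride: int = 25
    equilibration: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.solute_sites is None:
            h = self.site_separation / 2.0
            self.solute_sites = [
                (np.array([-h, 0.0, 0.0]), -1.0, AMINE_N10),
                (np.array([+h, 0.0, 0.0]), -1.0, PHOSPHATE_O),
                (np.array([0.0, 2.0, 0.0]), 0.0, OTHER),
                (np.array([0.0, -2.0, 0.0]), 0.0, OTHER),
            ]
        if self.mc_steps <= 0:
            raise ConfigurationError("mc_steps must be positive")
        if self.temperature <= 0:
            raise ConfigurationError("temperature must be positive")
        if self.lj_sigma <= 0 or self.lj_epsilon < 0:
            raise ConfigurationError("invalid Lennard-Jones parameters")


@dataclass
class ObservableModel:
    """Linear site-additive detachment-energy model with known truth.

    VDE = vde0 + sum over waters of the increment of the water's primary
    hydration site + Gaussian noise; ADE = VDE - relaxation_offset.
    """

    vde0: float = 1.30
    site_increments: dict[str, float] = field(
        default_factory=lambda: {"AMINE_N10": 0.50, "PHOSPHATE": 0.30}
    )
    noise_sd: float = 0.0
    relaxation_offset: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        # Increments are keyed by the hydration-site taxonomy labels.
        from .hydration import SITE_LABELS

        unknown = set(self.site_increments) - set(SITE_LABELS)
        if unknown:
            raise ConfigurationError(f"unknown site tags in model: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# geometry helpers

_OH = 0.9572
_HOH = math.radians(104.52)


def rigid_water(origin: np.ndarray) -> list[Atom]:
    """A rigid water with O at ``origin`` in a reference orientation."""
    o = np.asarray(origin, dtype=float)
    h1 = o + np.array([_OH, 0.0, 0.0])
    h2 = o + _OH * np.array([math.cos(_HOH), math.sin(_HOH), 0.0])
    return [Atom("O", o), Atom("H", h1), Atom("H", h2)]


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(angle * axis).as_matrix()


def build_toy_solute(params: ToyModelParams) -> Conformer:
    """Rigid toy dianion from ``params.solute_sites``.

    Elements follow the tags (amine site -> N, phosphate site -> O,
    neutral sites -> C); total charge is the sum of site charges and
    must include at least two charged sites.
    """
    if not params.solute_sites:
        raise ConfigurationError("solute_sites must be non-empty")
    n_charged = sum(1 for _, q, _ in params.solute_sites if abs(q) > 1e-12)
    if n_charged < 2:
        raise ConfigurationError("toy solute needs at least two charged sites")
    element_for = {AMINE_N10: "N", PHOSPHATE_O: "O"}
    atoms = [
        Atom(element_for.get(tag, "C"), np.asarray(pos, dtype=float), 0, tag)
        for pos, q, tag in params.solute_sites
    ]
    total = sum(q for _, q, _ in params.solute_sites)
    return Conformer("toy-solute", atoms, int(round(total)))


def _charges(conformer: Conformer, params: ToyModelParams) -> np.ndarray:
    """Per-atom charges: solute from params.solute_sites, waters from water_charges."""
    q = np.zeros(len(conformer.atoms))
    solute_q = [qq for _, qq, _ in params.solute_sites]
    i_sol = 0
    qo, qh = params.water_charges
    for i, a in enumerate(conformer.atoms):
        if a.fragment_id == 0:
            q[i] = solute_q[i_sol]
            i_sol += 1
        else:
            q[i] = qo if a.element == "O" else qh
    if i_sol != len(solute_q):
        raise ConfigurationError(
            "conformer solute atom count does not match params.solute_sites"
        )
    return q


def toy_energy(conformer: Conformer, params: ToyModelParams) -> float:
    """Total intermolecular energy, kcal/mol.

    Coulomb over all intermolecular pairs; LJ over heavy-atom
    intermolecular pairs.  Raises on overlapping atoms (r < 1e-6 A).
    """
    pos = conformer.positions
    q = _charges(conformer, params)
    frag = np.array([a.fragment_id for a in conformer.atoms])
    heavy = np.array([a.is_heavy for a in conformer.atoms])
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    inter = frag[:, None] != frag[None, :]
    iu = np.triu(inter, k=1)
    if np.any(d[iu] < 1e-6):
        raise FloatingPointError("overlapping atoms (r < 1e-6 A)")
    with np.errstate(divide="ignore"):
        e_coul = np.where(iu, COULOMB_KCAL * np.outer(q, q) / np.where(d > 0, d, 1.0), 0.0)
    lj_mask = iu & np.outer(heavy, heavy)
    sr6 = np.where(lj_mask, (params.lj_sigma / np.where(d > 0, d, 1.0)) ** 6, 0.0)
    e_lj = 4.0 * params.lj_epsilon * (sr6**2 - sr6)
    return float(e_coul[iu].sum() + e_lj[lj_mask].sum())


def metropolis_accept(delta_e: float, temperature: float, rng: np.random.Generator) -> bool:
    """Standard Metropolis criterion at ``temperature`` (kcal/mol input)."""
    if delta_e <= 0:
        return True
    return rng.random() < math.exp(-delta_e / (R_KCAL * temperature))


# ---------------------------------------------------------------------------
# sampler


def _water_interaction(pos, q, heavy, frag, fid, params) -> float:
    """Interaction energy of water ``fid`` with everything else."""
    sel = frag == fid
    p1, q1, h1 = pos[sel], q[sel], heavy[sel]
    p2, q2, h2 = pos[~sel], q[~sel], heavy[~sel]
    d = np.linalg.norm(p1[:, None, :] - p2[None, :, :], axis=-1)
    if np.any(d < 1e-6):
        return math.inf
    e = (COULOMB_KCAL * np.outer(q1, q2) / d).sum()
    lj = np.outer(h1, h2)
    if lj.any():
        sr6 = (params.lj_sigma / d[lj]) ** 6
        e += (4.0 * params.lj_epsilon * (sr6**2 - sr6)).sum()
    return float(e)


def sample_configurations(solute: Conformer, params: ToyModelParams) -> Ensemble:
    """Metropolis Monte Carlo over rigid-body water moves.

    Moves: random translation (each component uniform within
    +-max_translation), random rotation about the water oxygen (random
    axis, angle uniform within +-max_rotation), and with probability
    ``swap_probability`` a point inversion of one water through the
    solute charge centroid — a symmetric involution that lets waters
    hop between deep binding-site basins at 298 K — and with
    probability ``teleport_probability`` a random reinsertion (uniform
    position and orientation in the container), which keeps the chain
    ergodic across minor local minima.  Waters are confined
    to ``container_radius`` around the solute centroid.  Frames are
    recorded every ``stride`` accepted-or-rejected steps after
    ``equilibration`` steps.  Identical seeds give identical
    trajectories.
    """
    rng = np.random.default_rng(params.seed)
    center = np.mean([np.asarray(p) for p, _, _ in params.solute_sites], axis=0)
    charged = [np.asarray(p) for p, qq, _ in params.solute_sites if abs(qq) > 1e-12]
    inversion_center = np.mean(charged, axis=0) if charged else center

    atoms = [a.copy() for a in solute.atoms]
    # initial placement: waters on a circle around the container, then relaxed by MC
    for w in range(params.n_waters):
        theta = 2 * math.pi * rng.random()
        r0 = 0.6 * params.container_radius
        origin = center + r0 * np.array([math.cos(theta), math.sin(theta), 0.0])
        for at in rigid_water(origin):
            at.fragment_id = w + 1
            atoms.append(at)
    conf = Conformer("mc", atoms, solute.total_charge)

    pos = conf.positions
    q = _charges(conf, params)
    frag = np.array([a.fragment_id for a in conf.atoms])
    heavy = np.array([a.is_heavy for a in conf.atoms])
    max_rot = math.radians(params.max_rotation)

    frames: list[Conformer] = []
    n_accept = 0
    n_frame = 0
    for step in range(1, params.mc_steps + 1):
        fid = int(rng.integers(1, params.n_waters + 1))
        sel = frag == fid
        old = pos[sel].copy()
        e_old = _water_interaction(pos, q, heavy, frag, fid, params)

        new = old.copy()
        u = rng.random()
        if u < params.swap_probability:
            new = 2.0 * inversion_center - new  # point inversion (involution)
        elif u < params.swap_probability + params.teleport_probability:
            # random reinsertion: uniform position in the container sphere,
            # uniform orientation — symmetric proposal, escapes local minima
            while True:
                cand = rng.uniform(-1.0, 1.0, 3)
                if np.dot(cand, cand) <= 1.0:
                    break
            origin = center + params.container_radius * cand
            axis = rng.normal(size=3)
            rot = _rotation_matrix(axis, rng.uniform(0.0, 2.0 * math.pi))
            new = (old - old[0]) @ rot.T + origin
        else:
            axis = rng.normal(size=3)
            angle = rng.uniform(-max_rot, max_rot)
            rot = _rotation_matrix(axis, angle)
            pivot = new[0]  # oxygen
            new = (new - pivot) @ rot.T + pivot
            new = new + rng.uniform(-params.max_translation, params.max_translation, 3)

        if np.linalg.norm(new[0] - center) > params.container_radius:
            e_new = math.inf
        else:
            pos[sel] = new
            e_new = _water_interaction(pos, q, heavy, frag, fid, params)
            pos[sel] = old

        if e_new < math.inf and metropolis_accept(e_new - e_old, params.temperature, rng):
            pos[sel] = new
            n_accept += 1

        if step > params.equilibration and step % params.stride == 0:
            n_frame += 1
            snap = conf.copy(label=f"frame-{n_frame:05d}")
            snap.set_positions(pos)
            frames.append(snap)

    if n_accept == 0:
        logger.warning("Metropolis acceptance rate was exactly 0 over %d steps", params.mc_steps)
    if not frames:
        n_frame += 1
        snap = conf.copy(label=f"frame-{n_frame:05d}")
        snap.set_positions(pos)
        frames.append(snap)
    ens = Ensemble(frames, temperature=params.temperature)
    ens.validate()
    return ens


# ---------------------------------------------------------------------------
# synthetic observables


@dataclass
class SyntheticRecord:
    """Ground-truth-bearing detachment-energy record for one conformer."""

    label: str
    vde: float
    ade: float
    site_counts: dict[str, int]
    vde_truth: float  # noise-free value
    noise: float


def assign_synthetic_observables(
    representatives: Sequence[Conformer],
    model: ObservableModel,
    d_max: float = 3.5,
    angle_min: float = 140.0,
) -> list[SyntheticRecord]:
    """Site-additive VDE/ADE for each representative conformer.

    Hydration sites are classified geometrically (see
    :mod:`microsolv.hydration`); each occupied site adds its increment
    to ``vde0``.  With ``noise_sd = 0`` the record is exact and carries
    its own ground-truth decomposition for recovery tests.
    """
    from .hydration import classify_water_site, detect_hbonds

    rng = np.random.default_rng(model.seed)
    records: list[SyntheticRecord] = []
    for conf in representatives:
        hbonds = detect_hbonds(conf, d_max=d_max, angle_min=angle_min)
        counts: dict[str, int] = {}
        for fid in conf.water_fragment_ids():
            primary, _ = classify_water_site(conf, fid, hbonds)
            counts[primary] = counts.get(primary, 0) + 1
        vde_truth = model.vde0 + sum(
            model.site_increments.get(site, 0.0) * n for site, n in counts.items()
        )
        noise = float(rng.normal(0.0, model.noise_sd)) if model.noise_sd > 0 else 0.0
        vde = vde_truth + noise
        records.append(
            SyntheticRecord(
                label=conf.label,
                vde=vde,
                ade=vde - model.relaxation_offset,
                site_counts=counts,
                vde_truth=vde_truth,
                noise=noise,
            )
        )
    return records
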