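"""Geometric hydrogen-bond detection and hydration-site classification.

Where does each water bind?  For a doubly deprotonated nucleotide the
candidate sites are the deprotonated amine nitrogen (N10), the adjacent
carbonyl oxygen / purine ring, the phosphate oxygens, the ribose
hydroxyls, or another water.  Detection is purely geometric: a
donor-H...acceptor triplet counts as a hydrogen bond when the
donor-acceptor distance is at most ``d_max`` and the D-H...A angle at
least ``angle_min``.  Defaults d_max = 3.5 A, angle_min = 140 deg are
the common loose geometric criteria; both are configurable and recorded
in pipeline output metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .structures import (
    AMINE_N10 as TAG_AMINE_N10,
    PHOSPHATE_O as TAG_PHOSPHATE_O,
    PURINE_O11 as TAG_PURINE_O11,
    PURINE_RING_N as TAG_PURINE_RING_N,
    RIBOSE_OH as TAG_RIBOSE_OH,
    Conformer,
)

# Site taxonomy for occupancy bookkeeping (coarser than atom tags:
# the carbonyl O11 and ring nitrogens both count as "purine ring").
SITE_AMINE = "AMINE_N10"
SITE_PHOSPHATE = "PHOSPHATE"
SITE_PURINE_RING = "PURINE_RING"
SITE_RIBOSE_OH = "RIBOSE_OH"
SITE_WATER_WATER = "WATER_WATER"
SITE_NONE = "NONE"

SITE_LABELS = (
    SITE_AMINE,
    SITE_PHOSPHATE,
    SITE_PURINE_RING,
    SITE_RIBOSE_OH,
    SITE_WATER_WATER,
    SITE_NONE,
)

#: Priority used to choose a water's primary site when it bonds to several.
SITE_PRIORITY = (
    SITE_AMINE,
    SITE_PHOSPHATE,
    SITE_PURINE_RING,
    SITE_RIBOSE_OH,
    SITE_WATER_WATER,
)

_TAG_TO_SITE = {
    TAG_AMINE_N10: SITE_AMINE,
    TAG_PHOSPHATE_O: SITE_PHOSPHATE,
    TAG_PURINE_O11: SITE_PURINE_RING,
    TAG_PURINE_RING_N: SITE_PURINE_RING,
    TAG_RIBOSE_OH: SITE_RIBOSE_OH,
}

#: X-H covalent distance used to find hydrogens riding on a donor, A.
DONOR_H_CUTOFF = 1.2


@dataclass(frozen=True)
class HBond:
    """One donor-H...acceptor contact (atom indices into the conformer)."""

    donor: int
    hydrogen: int
    acceptor: int
    d_da: float
    angle_dha: float


def detect_hbonds(
    conformer: Conformer, d_max: float = 3.5, angle_min: float = 140.0
) -> list[HBond]:
    """All interfragment hydrogen bonds under the geometric criteria.

    Donors are N/O atoms with a covalently attached hydrogen (X-H
    < 1.2 A within the same fragment); acceptors are any N/O of a
    *different* fragment.
    """
    pos = conformer.positions
    elements = [a.element for a in conformer.atoms]
    frags = [a.fragment_id for a in conformer.atoms]
    n = len(conformer.atoms)

    candidates = [i for i in range(n) if elements[i] in ("N", "O")]
    hydrogens = [i for i in range(n) if elements[i] == "H"]

    # donor -> attached hydrogens
    attached: dict[int, list[int]] = {}
    for d in candidates:
        for h in hydrogens:
            if frags[h] == frags[d] and np.linalg.norm(pos[h] - pos[d]) < DONOR_H_CUTOFF:
                attached.setdefault(d, []).append(h)

    bonds: list[HBond] = []
    for d, hs in attached.items():
        for a in candidates:
            if frags[a] == frags[d] or a == d:
                continue
            d_da = float(np.linalg.norm(pos[a] - pos[d]))
            if d_da > d_max:
                continue
            for h in hs:
                v1 = pos[d] - pos[h]
                v2 = pos[a] - pos[h]
                cosang = float(
                    np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                )
                angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                if angle >= angle_min:
                    bonds.append(HBond(d, h, a, d_da, angle))
    return bonds


def classify_water_site(
    conformer: Conformer, water_id: int, hbonds: Iterable[HBond]
) -> tuple[str, list[str]]:
    """Primary site and full site multiset for one water.

    Every hydrogen bond the water participates in (as donor or
    acceptor) is mapped to the site label of the partner atom; a
    partner belonging to another water maps to WATER_WATER.  The
    primary label follows :data:`SITE_PRIORITY`; a water with no bonds
    is NONE.
    """
    if water_id not in conformer.water_fragment_ids():
        raise ValueError(f"no water fragment {water_id} in {conformer.label}")
    frags = [a.fragment_id for a in conformer.atoms]
    sites: list[str] = []
    for hb in hbonds:
        if frags[hb.donor] == water_id:
            partner = hb.acceptor
        elif frags[hb.acceptor] == water_id:
            partner = hb.donor
        else:
            continue
        if frags[partner] >= 1:
            sites.append(SITE_WATER_WATER)
        else:
            tag = conformer.atoms[partner].site_tag
            site = _TAG_TO_SITE.get(tag)
            if site is not None:
                sites.append(site)
    if not sites:
        return SITE_NONE, []
    for label in SITE_PRIORITY:
        if label in sites:
            return label, sites
    return SITE_NONE, sites


@dataclass
class SiteOccupancy:
    """Population-weighted water counts per hydration site."""

    counts: dict[str, float]
    total_weighted_waters: float
    d_max: float = 3.5
    angle_min: float = 140.0

    def ranking(self) -> list[tuple[str, float]]:
        """Sites sorted by descending weighted count (NONE included)."""
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))


def site_occupancy(
    representatives: Sequence[Conformer],
    fractions: dict[str, float],
    d_max: float = 3.5,
    angle_min: float = 140.0,
) -> SiteOccupancy:
    """Equilibrium-fraction-weighted site counts over an ensemble.

    ``fractions`` maps conformer label -> equilibrium fraction x_M.
    The total weighted water count equals sum_M x_M * n_waters(M).
    """
    missing = [c.label for c in representatives if c.label not in fractions]
    if missing:
        raise KeyError(f"no equilibrium fraction for conformer(s) {missing}")
    counts = {label: 0.0 for label in SITE_LABELS}
    total = 0.0
    for conf in representatives:
        x = fractions[conf.label]
        hbonds = detect_hbonds(conf, d_max=d_max, angle_min=angle_min)
        for fid in conf.water_fragment_ids():
            primary, _ = classify_water_site(conf, fid, hbonds)
            counts[primary] += x
            total += x
    return SiteOccupancy(counts, total, d_max, angle_min)
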