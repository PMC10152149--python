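"""Back-of-envelope estimates for a cylindrical microwell comet assay.

All operations return exact floating-point values; significant-figure
rounding (the convention used when quoting such estimates) is applied
explicitly via :func:`round_sig` or by the report builder, never silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "MicrowellGeometry",
    "EstimateConstants",
    "EstimateReport",
    "round_sig",
    "well_volume",
    "molecule_count",
    "subunits_to_length",
    "filaments_per_cross_section",
    "mesh_size",
    "filament_count",
    "arp_fraction",
    "pool_length_equivalent",
    "bead_density_ratio",
    "build_report",
]


def round_sig(x: float, n: int) -> float:
    """Round ``x`` to ``n`` significant figures (0 stays 0)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (n - 1))


@dataclass(frozen=True)
class MicrowellGeometry:
    """Cylindrical well; ``pi_mode`` selects exact pi or the rough pi ~ 3."""

    radius_um: float = 50.0
    height_um: float = 20.0
    pi_mode: str = "paper"  # "paper" (pi ~ 3) or "exact"

    def __post_init__(self) -> None:
        if self.radius_um <= 0 or self.height_um <= 0:
            raise ValueError("radius and height must be positive")
        if self.pi_mode not in ("paper", "exact"):
            raise ValueError("pi_mode must be 'paper' or 'exact'")

    @property
    def pi(self) -> float:
        return 3.0 if self.pi_mode == "paper" else math.pi


@dataclass(frozen=True)
class EstimateConstants:
    """Fixed conversion constants for the estimates."""

    omega_per_uM_um3: float = 600.0      # molecules per (uM * um^3)
    subunit_rise_um: float = 0.0027      # length added per subunit
    mean_filament_length_um: float = 0.3

    def __post_init__(self) -> None:
        for name in ("omega_per_uM_um3", "subunit_rise_um", "mean_filament_length_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def well_volume(geom: MicrowellGeometry) -> float:
    """Cylinder volume ``pi R^2 H`` in um^3 (pi per the geometry's mode)."""
    return geom.pi * geom.radius_um**2 * geom.height_um


def molecule_count(conc_uM: float, volume_um3: float, omega: float = 600.0) -> float:
    """Number of molecules at ``conc_uM`` in ``volume_um3``."""
    if conc_uM < 0 or volume_um3 < 0 or omega < 0:
        raise ValueError("inputs must be nonnegative")
    return omega * volume_um3 * conc_uM


def subunits_to_length(n_subunits: float, subunit_rise_um: float = 0.0027) -> float:
    """Total filament length (um) contributed by ``n_subunits`` subunits."""
    if n_subunits < 0 or subunit_rise_um < 0:
        raise ValueError("inputs must be nonnegative")
    return n_subunits * subunit_rise_um


def filaments_per_cross_section(total_length_um: float, tail_length_um: float) -> float:
    """Filaments crossing any tail section: total filament length / tail length."""
    if tail_length_um <= 0:
        raise ValueError("tail_length_um must be positive")
    return total_length_um / tail_length_um


def mesh_size(cross_section_um2: float, n_fil: float) -> float:
    """Mean inter-filament spacing sqrt(area / N_fil), in nm."""
    if cross_section_um2 <= 0 or n_fil <= 0:
        raise ValueError("inputs must be positive")
    return math.sqrt(cross_section_um2 / n_fil) * 1000.0


def filament_count(total_length_um: float, mean_filament_length_um: float) -> float:
    """Number of filaments: total length / mean filament length."""
    if mean_filament_length_um <= 0:
        raise ValueError("mean_filament_length_um must be positive")
    return total_length_um / mean_filament_length_um


def arp_fraction(n_filaments: float, n_arp_total: float) -> float:
    """Percent of the Arp2/3 pool bound in the tail (one complex per filament)."""
    if n_arp_total <= 0:
        raise ValueError("n_arp_total must be positive")
    return 100.0 * n_filaments / n_arp_total


def pool_length_equivalent(mean_comet_length_um: float, tail_fraction: float) -> float:
    """Length-equivalent of the whole monomer pool: comet length / tail fraction."""
    if not 0.0 < tail_fraction <= 1.0:
        raise ValueError("tail_fraction must be in (0, 1]")
    return mean_comet_length_um / tail_fraction


def bead_density_ratio(n1: float, vol1: float, n2: float, vol2: float) -> float:
    """Ratio of number densities (n1/vol1) / (n2/vol2)."""
    if min(n1, vol1, n2, vol2) <= 0:
        raise ValueError("inputs must be positive")
    return (n1 / vol1) / (n2 / vol2)


@dataclass(frozen=True)
class EstimateReport:
    """Exact and significant-figure-rounded estimates, with provenance notes."""

    exact: dict = field(default_factory=dict)
    rounded: dict = field(default_factory=dict)
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"exact": dict(self.exact), "rounded": dict(self.rounded), "notes": dict(self.notes)}


def build_report(
    geom: MicrowellGeometry | None = None,
    constants: EstimateConstants | None = None,
    *,
    actin_uM: float = 3.0,
    arp_uM: float = 0.09,
    capping_uM: float = 0.015,
    assembled_fraction: float = 0.5,
    max_tail_um: float = 60.0,
    cross_section_um2: float = 12.0,
    mean_comet_length_um: float = 63.0,
    measured_tail_fraction: float = 0.57,
    beads_per_well: float = 1.0,
    well_volume_pl: float = 140.0,
    beads_per_field: float = 20.0,
    field_volume_pl: float = 120000.0,
) -> EstimateReport:
    """Full estimate pipeline for one microwell experiment.

    Each downstream quantity is computed from the *rounded* value of its
    inputs, mirroring how chained order-of-magnitude estimates are quoted
    (e.g. the subunit count is rounded to one significant figure before
    being converted into filament length).
    """
    geom = geom or MicrowellGeometry()
    constants = constants or EstimateConstants()

    exact: dict[str, float] = {}
    rounded: dict[str, float] = {}
    notes: dict[str, str] = {}

    vol = well_volume(geom)
    exact["volume_um3"] = vol
    rounded["volume_um3"] = round_sig(vol, 2)
    notes["volume_um3"] = f"pi R^2 H with pi_mode={geom.pi_mode}, R={geom.radius_um}, H={geom.height_um}"

    n_actin = molecule_count(actin_uM, rounded["volume_um3"], constants.omega_per_uM_um3)
    exact["n_actin_subunits"] = n_actin
    rounded["n_actin_subunits"] = round_sig(n_actin, 1)
    notes["n_actin_subunits"] = f"omega * W * {actin_uM} uM, one significant figure"

    n_in_tail = assembled_fraction * rounded["n_actin_subunits"]
    exact["n_subunits_in_tail"] = n_in_tail
    rounded["n_subunits_in_tail"] = round_sig(n_in_tail, 2)
    notes["n_subunits_in_tail"] = f"{assembled_fraction:.0%} of the pool assembled into the tail"

    total_len = subunits_to_length(n_in_tail, constants.subunit_rise_um)
    exact["total_filament_length_um"] = total_len
    rounded["total_filament_length_um"] = round_sig(total_len, 1)
    notes["total_filament_length_um"] = f"subunits * {constants.subunit_rise_um} um rise, one significant figure"

    n_fil_cs = filaments_per_cross_section(rounded["total_filament_length_um"], max_tail_um)
    exact["n_fil_cross_section"] = n_fil_cs
    rounded["n_fil_cross_section"] = round_sig(n_fil_cs, 2)
    notes["n_fil_cross_section"] = f"total filament length / max tail length {max_tail_um} um, two significant figures"

    zeta = mesh_size(cross_section_um2, rounded["n_fil_cross_section"])
    exact["mesh_size_nm"] = zeta
    rounded["mesh_size_nm"] = round_sig(zeta, 1)
    notes["mesh_size_nm"] = f"sqrt(area {cross_section_um2} um^2 / N_fil), one significant figure"

    n_fil = filament_count(rounded["total_filament_length_um"], constants.mean_filament_length_um)
    exact["filament_count"] = n_fil
    rounded["filament_count"] = round_sig(n_fil, 2)
    notes["filament_count"] = f"total length / mean filament length {constants.mean_filament_length_um} um"

    n_arp = molecule_count(arp_uM, rounded["volume_um3"], constants.omega_per_uM_um3)
    exact["n_arp"] = n_arp
    rounded["n_arp"] = round_sig(n_arp, 1)
    notes["n_arp"] = f"omega * W * {arp_uM} uM, one significant figure"

    n_cp = molecule_count(capping_uM, rounded["volume_um3"], constants.omega_per_uM_um3)
    exact["n_capping"] = n_cp
    rounded["n_capping"] = round_sig(n_cp, 2)
    notes["n_capping"] = f"omega * W * {capping_uM} uM (exact value; quoted counts round up)"

    frac = arp_fraction(rounded["filament_count"], rounded["n_arp"])
    exact["arp_fraction_percent"] = frac
    rounded["arp_fraction_percent"] = round_sig(frac, 2)
    notes["arp_fraction_percent"] = "one Arp2/3 complex per filament, percent of total pool"

    pool = pool_length_equivalent(mean_comet_length_um, measured_tail_fraction)
    exact["pool_length_um"] = pool
    rounded["pool_length_um"] = round_sig(pool, 2)
    notes["pool_length_um"] = (
        f"mean comet length {mean_comet_length_um} um / measured tail fraction {measured_tail_fraction}"
    )

    ratio = bead_density_ratio(beads_per_well, well_volume_pl, beads_per_field, field_volume_pl)
    exact["bead_density_ratio"] = ratio
    rounded["bead_density_ratio"] = round_sig(ratio, 1)
    notes["bead_density_ratio"] = "(beads/well volume) / (beads/field volume), order of magnitude"

    return EstimateReport(exact=exact, rounded=rounded, notes=notes)
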