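"""Genome-packaging arithmetic.

Relates capsid capacity to genome load: bases of packaged RNA per Gag
subunit and interior volume per packaged base.  Defaults are not baked in;
the caller supplies genome length (kb), genome copy number, Gag (CA
subunit) count — directly or as 60*T via the lattice census — and the
capsid interior volume in nm^3.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor, log10, pi

from .tnumber import lattice_census

__all__ = ["PackagingReport", "packaging_stats", "sphere_volume_nm3", "round_1sf"]


def round_1sf(x: float) -> float:
    """Round to one significant figure (the ~ convention of back-of-envelope
    packaging numbers)."""
    if x == 0:
        return 0.0
    exp = floor(log10(abs(x)))
    return round(x, -exp)


def sphere_volume_nm3(inner_radius_nm: float) -> float:
    """(4/3) pi r^3 — an optional helper for a user-chosen interior radius.

    Which radius bounds the interior (center of the CA layer vs its inner
    surface) is a modelling choice; this helper just does the geometry.
    """
    if not inner_radius_nm > 0:
        raise ValueError("inner_radius_nm must be positive")
    return 4.0 / 3.0 * pi * inner_radius_nm**3


@dataclass
class PackagingReport:
    genome_kb: float
    genome_copies: int
    gag_count: int
    interior_volume_nm3: float
    bases_per_gag: float
    nm3_per_base: float
    bases_per_gag_1sf: float
    nm3_per_base_1sf: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def packaging_stats(
    genome_kb: float,
    genome_copies: int,
    gag_count: int = None,
    interior_volume_nm3: float = None,
    *,
    T: int = None,
) -> PackagingReport:
    """Packaging statistics for one capsid.

    ``gag_count`` may be given directly or derived as 60*T from the
    triangulation number.  Exact identities:

    - bases_per_gag = 1000 * genome_kb * genome_copies / gag_count
    - nm3_per_base  = interior_volume_nm3 / (1000 * genome_kb * genome_copies)

    so bases_per_gag * gag_count * nm3_per_base == interior_volume_nm3.
    One-significant-figure roundings are reported alongside the raw values.
    """
    if gag_count is None:
        if T is None:
            raise ValueError("supply gag_count or T")
        gag_count = lattice_census(T).n_subunits
    genome_copies = int(genome_copies)
    gag_count = int(gag_count)
    if not (genome_kb > 0 and genome_copies > 0 and gag_count > 0):
        raise ValueError("genome_kb, genome_copies and gag_count must be positive")
    if interior_volume_nm3 is None or not interior_volume_nm3 > 0:
        raise ValueError("interior_volume_nm3 must be positive")

    bases = 1000.0 * genome_kb * genome_copies
    bases_per_gag = bases / gag_count
    nm3_per_base = interior_volume_nm3 / bases
    return PackagingReport(
        genome_kb=float(genome_kb),
        genome_copies=genome_copies,
        gag_count=gag_count,
        interior_volume_nm3=float(interior_volume_nm3),
        bases_per_gag=bases_per_gag,
        nm3_per_base=nm3_per_base,
        bases_per_gag_1sf=round_1sf(bases_per_gag),
        nm3_per_base_1sf=round_1sf(nm3_per_base),
    )
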