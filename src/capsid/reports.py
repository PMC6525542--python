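"""Per-particle and per-dataset analysis reports.

Ties the neighbor graph, capsomer classification, closure check and
T-number walks into one structured report per particle, and aggregates
cohorts the way particle datasets are summarised: fraction of complete
closed shells, fraction of particles with mixed T-numbers, and the T
spectrum of the complete particles.
"""

from __future__ import annotations

import logging
from typing import Iterable, List

import pandas as pd

from .graph import (
    CLASS_EDGE,
    build_graph,
    classify_capsomers,
    closure_report,
)
from .synth import CapsomerSet
from .tnumber import VERDICT_ICOSAHEDRAL, VERDICT_MIXED, particle_t

__all__ = ["analyze_particle", "analyze_batch"]

logger = logging.getLogger(__name__)


def analyze_particle(
    cs: CapsomerSet,
    cutoff_factor: float = 1.4,
    *,
    method: str = "auto",
) -> dict:
    """Full lattice analysis of one particle.

    Returns a JSON-ready dict with the closure report, per-class capsomer
    counts (boundary ``edge`` capsomers counted separately, never folded
    into the three symmetry classes), and the T-number report.
    """
    lg = classify_capsomers(build_graph(cs, cutoff_factor, method=method))
    closure = closure_report(lg)
    trep = particle_t(lg)
    counts = lg.class_counts
    if counts[CLASS_EDGE]:
        logger.warning("particle %s: %d boundary/unclassifiable capsomers "
                       "excluded from class statistics",
                       cs.particle_id, counts[CLASS_EDGE])
    n_unresolved = sum(1 for p in trep.pairs if not p.resolved)
    if n_unresolved:
        logger.warning("particle %s: %d pentamer pair(s) without a "
                       "hexamer-only corridor left unresolved",
                       cs.particle_id, n_unresolved)
    return {
        "particle_id": cs.particle_id,
        "n_capsomers": len(cs),
        "adjacency_mode": lg.adjacency_mode,
        "closure": {
            "complete": closure.complete,
            "n_pentamers": closure.n_pentamers,
            "n_hexamers": closure.n_hexamers,
            "disclination_sum": closure.disclination_sum,
        },
        "class_counts": {
            "fivefold": counts["fivefold"],
            "pseudothreefold": counts["pseudothreefold"],
            "threefold": counts["threefold"],
        },
        "n_excluded_boundary": counts[CLASS_EDGE],
        "t_report": {
            "verdict": trep.verdict,
            "T": trep.T,
            "T_values": trep.T_values,
            "global_T_from_count": trep.global_T_from_count,
            "pairs": [
                {"pent_i": p.pent_i, "pent_j": p.pent_j,
                 "h": p.h, "k": p.k, "T_local": p.T}
                for p in trep.pairs
            ],
            "n_unresolved_pairs": sum(1 for p in trep.pairs if not p.resolved),
        },
    }


def analyze_batch(
    sets: Iterable[CapsomerSet],
    cutoff_factor: float = 1.4,
    *,
    method: str = "auto",
) -> dict:
    """Analyse a cohort of particles and aggregate dataset statistics.

    Returns ``{"particles": [...], "summary": {...}, "table": DataFrame}``
    where the summary reports the fraction of complete closed shells, the
    fraction of particles with mixed T-numbers, and the T-number spectrum
    of the complete icosahedral particles.
    """
    particles: List[dict] = [
        analyze_particle(cs, cutoff_factor, method=method) for cs in sets
    ]
    n = len(particles)
    if n == 0:
        raise ValueError("empty particle cohort")
    n_complete = sum(p["closure"]["complete"] for p in particles)
    n_mixed = sum(p["t_report"]["verdict"] == VERDICT_MIXED for p in particles)
    t_spectrum: dict = {}
    for p in particles:
        if p["t_report"]["verdict"] == VERDICT_ICOSAHEDRAL:
            t_spectrum[p["t_report"]["T"]] = t_spectrum.get(p["t_report"]["T"], 0) + 1
    table = pd.DataFrame(
        [
            {
                "particle_id": p["particle_id"],
                "n_capsomers": p["n_capsomers"],
                "complete": p["closure"]["complete"],
                "n_pentamers": p["closure"]["n_pentamers"],
                "verdict": p["t_report"]["verdict"],
                "T": p["t_report"]["T"],
            }
            for p in particles
        ]
    )
    summary = {
        "n_particles": n,
        "n_complete": n_complete,
        "fraction_complete": n_complete / n,
        "n_mixed": n_mixed,
        "fraction_mixed": n_mixed / n,
        "t_spectrum_complete": dict(sorted(t_spectrum.items())),
    }
    return {"particles": particles, "summary": summary, "table": table}
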