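"""Conventional structure calculation by torsion-space simulated annealing.

A multi-start Metropolis annealer stands in for torsion-angle dynamics: the
energy is the restraint target function (squared distance- and
dihedral-bound violations) plus a weakly weighted physical prior, the
temperature and single-torsion move width follow geometric schedules, and
the best-so-far conformer of each trajectory is retained.  The lowest-target
conformer over all starts seeds the Bayesian refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .molecule import PriorParams, TorsionConformer, get_template, \
    _normalize_sequence
from .noe_restraints import DIHEDRAL_WEIGHT, compile_dihedrals, \
    compile_restraints

__all__ = ["AnnealConfig", "run_annealing", "select_seed"]


@dataclass
class AnnealConfig:
    """Multi-start annealing schedule.

    Temperatures are in target-function units (Angstrom^2); move widths in
    degrees.  Both schedules are geometric over ``n_steps``.
    """

    n_starts: int = 100
    n_steps: int = 10000
    t_start: float = 50.0
    t_end: float = 0.1
    width_start: float = 30.0
    width_end: float = 2.0
    prior_weight: float = 0.05  # weight of the physical prior in the energy
    dihedral_weight: float = DIHEDRAL_WEIGHT
    seed: int = 0

    def __post_init__(self):
        if self.n_starts < 1 or self.n_steps < 1:
            raise ValueError("n_starts and n_steps must be >= 1")


def _start_seed(master: int, start: int) -> int:
    return int(np.random.SeedSequence((master, start)).generate_state(1)[0]
               % (2**31 - 1))


def run_annealing(sequence, restraints, config: AnnealConfig | None = None,
                  dihedrals=()):
    """Anneal ``n_starts`` random conformers against the restraints.

    Returns a list of ``(TorsionConformer, target_value)`` sorted by
    ascending restraint target (ties keep start order).  Deterministic for
    a given config seed; each trajectory reports its best-so-far state, so
    the final target never exceeds the initial one.
    """
    config = config or AnnealConfig()
    seq = _normalize_sequence(sequence)
    tpl = get_template(seq)
    R = compile_restraints(tpl, restraints)
    D = compile_dihedrals(tpl, dihedrals, config.dihedral_weight)
    prior = PriorParams()

    results = []
    for s in range(config.n_starts):
        sub = np.random.default_rng(_start_seed(config.seed, s))
        # i.i.d. uniform start on (-pi, pi]
        t0 = np.pi - sub.random(tpl.n_torsions) * 2.0 * np.pi
        best, best_t, _best_e = _kernels.anneal_run(
            t0, tpl.ref_a, tpl.ref_b, tpl.ref_c, tpl.bond, tpl.angle,
            tpl.tor_base, tpl.tor_idx,
            R["opt_i"], R["opt_j"], R["opt_start"], R["opt_end"],
            R["lower"], R["upper"],
            D["dih_idx"], D["dih_lo"], D["dih_hi"], D["dih_weight"],
            tpl.pair_i, tpl.pair_j, tpl.pair_rmin,
            prior.k_rep, prior.k_tor, config.prior_weight,
            config.n_steps,
            config.t_start, config.t_end,
            np.radians(config.width_start), np.radians(config.width_end),
            _start_seed(config.seed, 10_000 + s),
        )
        results.append((TorsionConformer(seq, np.degrees(best)),
                        float(best_t)))
    order = np.argsort([t for (_c, t) in results], kind="stable")
    return [results[k] for k in order]


def select_seed(conformers):
    """Lowest-target conformer; ties broken by lowest index."""
    if not conformers:
        raise ValueError("empty annealing result")
    best = 0
    for k in range(1, len(conformers)):
        if conformers[k][1] < conformers[best][1]:
            best = k
    return conformers[best][0]
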