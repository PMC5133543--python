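"""Bayesian structure refinement by replica-exchange Monte Carlo.

The joint posterior over the conformation X and per-spectrum nuisance
parameters (log calibration constant c_s, noise scale sigma_s) is

    log pi(X, c, sigma) =
        sum_s sum_{k in s} [ -(ln I_k - (c_s - 6 ln r_eff,k(X)))^2
                             / (2 sigma_s^2) - ln sigma_s ]
      + sum_s ln N(c_s; mu0, tau0^2)
      + sum_s ln InvGamma(sigma_s^2; alpha0, beta0)
      - E_prior(X)

i.e. a normal likelihood on log intensities (which makes the normal /
inverse-gamma nuisance priors exactly conjugate and respects intensity
positivity), ambiguity-aware effective distances, and the simplified
physical prior energy in k_B T units.

Sampling runs K tempered replicas (temperatures geometric between 300 and
400 K; beta_k = T_1/T_k scales the full log-posterior) of a hybrid kernel:
single-torsion Metropolis sweeps (compiled), an occasional gradient-informed
collective move over all torsions (MALA with finite-difference gradients and
the proposal-asymmetry correction), and conjugate Gibbs updates of the
nuisance parameters.  Adjacent replicas periodically attempt state swaps
with the standard exchange acceptance.  Ensemble snapshots are taken from
the T = 300 K chain only and thinned after burn-in.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from . import _kernels
from .molecule import (PriorParams, TorsionConformer, build_coordinates,
                       get_template)
from .noe_restraints import compile_restraints

__all__ = [
    "Hyper",
    "NuisanceState",
    "PosteriorState",
    "ReplicaLadder",
    "RexmcConfig",
    "Trace",
    "StructuralModel",
    "build_ladder",
    "log_posterior",
    "gibbs_update_c",
    "gibbs_update_sigma",
    "hybrid_move",
    "exchange_attempt",
    "run_rexmc",
    "burn_and_thin",
    "map_state",
]


@dataclass(frozen=True)
class Hyper:
    """Hyperparameters of the nuisance priors.

    ``mu0/tau0``: mean and sd of the normal prior on c_s = ln C_s (log
    units); ``alpha0/beta0``: shape and scale of the inverse-gamma prior on
    sigma_s^2.
    """

    mu0: float = 0.0
    tau0: float = 2.0
    alpha0: float = 2.0
    beta0: float = 0.5


@dataclass
class NuisanceState:
    """Per-spectrum calibration and noise-scale parameters."""

    spectrum_ids: list
    log_c: np.ndarray   # c_s = ln C_s
    sigma: np.ndarray   # sigma_s > 0

    def __post_init__(self):
        self.log_c = np.asarray(self.log_c, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma <= 0):
            raise ValueError("noise scales sigma_s must be > 0")

    def copy(self):
        return NuisanceState(list(self.spectrum_ids), self.log_c.copy(),
                             self.sigma.copy())


@dataclass
class PosteriorState:
    """Conformer plus nuisance parameters with cached log densities."""

    conformer: TorsionConformer
    nuisance: NuisanceState
    log_prior: float = np.nan
    log_likelihood: float = np.nan
    log_posterior: float = np.nan

    def copy(self):
        return PosteriorState(
            TorsionConformer(self.conformer.sequence,
                             self.conformer.angles.copy()),
            self.nuisance.copy(), self.log_prior, self.log_likelihood,
            self.log_posterior)


@dataclass(frozen=True)
class ReplicaLadder:
    temperatures: tuple

    def __post_init__(self):
        t = np.asarray(self.temperatures)
        if t.ndim != 1 or len(t) < 1 or np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")

    @property
    def betas(self) -> np.ndarray:
        t = np.asarray(self.temperatures)
        return t[0] / t

    def __len__(self):
        return len(self.temperatures)


def build_ladder(n_replicas: int = 10, t_min: float = 300.0,
                 t_max: float = 400.0) -> ReplicaLadder:
    """Geometric temperature ladder with exact endpoints."""
    if n_replicas == 1:
        return ReplicaLadder((t_min,))
    k = np.arange(n_replicas)
    temps = t_min * (t_max / t_min) ** (k / (n_replicas - 1))
    temps[0], temps[-1] = t_min, t_max
    return ReplicaLadder(tuple(temps))


# ---------------------------------------------------------------------------
# the structural posterior model


class StructuralModel:
    """Compiled posterior of a sequence + restraint set (see module doc)."""

    def __init__(self, sequence, restraints, hyper: Hyper | None = None,
                 prior_params: PriorParams | None = None,
                 spectrum_ids=None):
        from .molecule import _normalize_sequence

        self.template = get_template(_normalize_sequence(sequence))
        self.restraints = list(restraints)
        self.hyper = hyper or Hyper()
        self.prior_params = prior_params or PriorParams()
        self.R = compile_restraints(self.template, self.restraints)
        if np.any(~np.isfinite(self.R["log_intensity"])):
            raise ValueError(
                "all restraints need positive source-peak intensities for "
                "the Bayesian likelihood"
            )
        if spectrum_ids is not None:
            # align restraint spectra to an external ordering (which may
            # include spectra without restraints)
            remap = {k: spectrum_ids.index(sid)
                     for k, sid in enumerate(self.R["spectrum_ids"])}
            self.R["spectrum_index"] = np.array(
                [remap[k] for k in self.R["spectrum_index"]],
                dtype=np.int64)
            self.spectrum_ids = list(spectrum_ids)
        else:
            self.spectrum_ids = self.R["spectrum_ids"]

    # -- log densities ------------------------------------------------------
    def _stats(self, coords, nuis: NuisanceState):
        return _kernels.loglik_and_stats(
            coords, self.R["opt_i"], self.R["opt_j"], self.R["opt_start"],
            self.R["opt_end"], self.R["log_intensity"],
            self.R["spectrum_index"], nuis.log_c, nuis.sigma)

    def log_posterior(self, state: PosteriorState, update: bool = True
                      ) -> float:
        h = self.hyper
        coords = state.conformer.template.build(state.conformer.angles)
        ll, _n, _so, _ss = self._stats(coords, state.nuisance)
        torsions = np.radians(state.conformer.angles)
        e_prior = _kernels.prior_energy_arrays(
            coords, torsions, self.template.pair_i, self.template.pair_j,
            self.template.pair_rmin, self.prior_params.k_rep,
            self.prior_params.k_tor)
        lp_nuis = 0.0
        for s in range(len(state.nuisance.log_c)):
            c = state.nuisance.log_c[s]
            sig2 = state.nuisance.sigma[s] ** 2
            lp_nuis += (-0.5 * np.log(2 * np.pi * h.tau0**2)
                        - (c - h.mu0) ** 2 / (2 * h.tau0**2))
            lp_nuis += (h.alpha0 * np.log(h.beta0) - gammaln(h.alpha0)
                        - (h.alpha0 + 1) * np.log(sig2) - h.beta0 / sig2)
        lp = float(ll) + lp_nuis - float(e_prior)
        if update:
            state.log_likelihood = float(ll)
            state.log_prior = lp_nuis - float(e_prior)
            state.log_posterior = lp
        return lp

    # -- Gibbs conditionals --------------------------------------------------
    def gibbs_c(self, state: PosteriorState, s: int, rng, beta: float = 1.0):
        h = self.hyper
        coords = state.conformer.template.build(state.conformer.angles)
        _ll, n_k, sum_obs, _ss = self._stats(coords, state.nuisance)
        n_s = n_k[s]
        sig2 = state.nuisance.sigma[s] ** 2
        prec = 1.0 / h.tau0**2 + n_s / sig2
        mean = (h.mu0 / h.tau0**2 + sum_obs[s] / sig2) / prec
        state.nuisance.log_c[s] = rng.normal(mean, 1.0 / np.sqrt(beta * prec))
        return state.nuisance.log_c[s]

    def gibbs_sigma(self, state: PosteriorState, s: int, rng,
                    beta: float = 1.0):
        h = self.hyper
        coords = state.conformer.template.build(state.conformer.angles)
        _ll, n_k, _so, ss = self._stats(coords, state.nuisance)
        n_s = n_k[s]
        if beta == 1.0:
            shape = h.alpha0 + 0.5 * n_s
            scale = h.beta0 + 0.5 * ss[s]
        else:  # tempered conditional of the full posterior^beta
            shape = beta * (h.alpha0 + 1.0 + 0.5 * n_s) - 1.0
            scale = beta * (h.beta0 + 0.5 * ss[s])
        sig2 = scale / rng.gamma(shape)
        state.nuisance.sigma[s] = np.sqrt(sig2)
        return state.nuisance.sigma[s]

    # -- move kernels --------------------------------------------------------
    def segment(self, state: PosteriorState, beta: float, n_steps: int,
                width_rad: float, seed: int):
        """Compiled single-torsion Metropolis sweep; updates in place."""
        tpl = self.template
        t, lp, acc = _kernels.posterior_chain_segment(
            np.radians(state.conformer.angles), state.nuisance.log_c,
            state.nuisance.sigma, beta, n_steps, width_rad,
            tpl.ref_a, tpl.ref_b, tpl.ref_c, tpl.bond, tpl.angle,
            tpl.tor_base, tpl.tor_idx,
            self.R["opt_i"], self.R["opt_j"], self.R["opt_start"],
            self.R["opt_end"], self.R["log_intensity"],
            self.R["spectrum_index"],
            tpl.pair_i, tpl.pair_j, tpl.pair_rmin,
            self.prior_params.k_rep, self.prior_params.k_tor,
            self.hyper.mu0, self.hyper.tau0, self.hyper.alpha0,
            self.hyper.beta0, seed)
        state.conformer = TorsionConformer(state.conformer.sequence,
                                           np.degrees(t))
        return state, int(acc)

    def _lp_torsions(self, angles_deg, nuis):
        coords = self.template.build(angles_deg)
        ll, _n, _so, _ss = self._stats(coords, nuis)
        e_prior = _kernels.prior_energy_arrays(
            coords, np.radians(angles_deg), self.template.pair_i,
            self.template.pair_j, self.template.pair_rmin,
            self.prior_params.k_rep, self.prior_params.k_tor)
        return float(ll) - float(e_prior)

    def grad_torsions(self, angles_deg, nuis, eps_deg: float = 0.25):
        """Central finite-difference gradient of the torsion-dependent part
        of the log posterior, per degree."""
        g = np.zeros_like(angles_deg)
        for k in range(len(angles_deg)):
            up = angles_deg.copy()
            dn = angles_deg.copy()
            up[k] += eps_deg
            dn[k] -= eps_deg
            g[k] = (self._lp_torsions(up, nuis)
                    - self._lp_torsions(dn, nuis)) / (2 * eps_deg)
        return g


# ---------------------------------------------------------------------------
# module-level operations (thin wrappers over the model)


def log_posterior(state: PosteriorState, restraints,
                  hyper: Hyper | None = None,
                  prior_params: PriorParams | None = None) -> float:
    """Full joint log posterior of a state given restraints (see module doc)."""
    model = StructuralModel(state.conformer.sequence, restraints, hyper,
                            prior_params)
    return model.log_posterior(state)


def gibbs_update_c(state: PosteriorState, spectrum_id: str, restraints,
                   rng, hyper: Hyper | None = None) -> float:
    """Draw c_s from its conjugate normal conditional.

    precision = 1/tau0^2 + n_s/sigma_s^2;
    mean = (mu0/tau0^2 + sum_k (ln I_k + 6 ln r_eff,k)/sigma_s^2)/precision.
    With no restraints in the spectrum this reduces to the prior.
    """
    model = StructuralModel(state.conformer.sequence, restraints, hyper,
                            spectrum_ids=list(state.nuisance.spectrum_ids))
    s = _spectrum_index(state, spectrum_id)
    return model.gibbs_c(state, s, rng)


def gibbs_update_sigma(state: PosteriorState, spectrum_id: str, restraints,
                       rng, hyper: Hyper | None = None) -> float:
    """Draw sigma_s^2 from IG(alpha0 + n_s/2, beta0 + SS_s/2)."""
    model = StructuralModel(state.conformer.sequence, restraints, hyper,
                            spectrum_ids=list(state.nuisance.spectrum_ids))
    s = _spectrum_index(state, spectrum_id)
    return model.gibbs_sigma(state, s, rng)


def _spectrum_index(state: PosteriorState, spectrum_id: str) -> int:
    try:
        return state.nuisance.spectrum_ids.index(spectrum_id)
    except ValueError:
        raise KeyError(f"unknown spectrum {spectrum_id!r}")


@dataclass
class StepConfig:
    width_deg: float = 8.0       # single-torsion Gaussian width
    mala_eps_deg: float = 1.5    # collective-move step scale
    p_collective: float = 0.2


def hybrid_move(state: PosteriorState, model: StructuralModel, rng,
                step_config: StepConfig | None = None, beta: float = 1.0,
                kind: str | None = None):
    """One hybrid Monte Carlo move; returns (state, accepted).

    Kind 'single': Gaussian perturbation of one torsion (symmetric
    proposal).  Kind 'collective': MALA over all torsions with
    finite-difference gradients and the proposal-asymmetry correction -
    the surrogate for the molecular-dynamics leg.  If ``kind`` is None it
    is chosen at random with probability ``p_collective``.
    """
    cfg = step_config or StepConfig()
    if kind is None:
        kind = "collective" if rng.random() < cfg.p_collective else "single"
    ang = state.conformer.angles
    nuis = state.nuisance
    cur_lp = model._lp_torsions(ang, nuis)
    if kind == "single":
        k = int(rng.integers(len(ang)))
        prop = ang.copy()
        prop[k] = _wrap_deg(prop[k] + rng.normal(0.0, cfg.width_deg))
        new_lp = model._lp_torsions(prop, nuis)
        log_alpha = beta * (new_lp - cur_lp)
    else:
        eps = cfg.mala_eps_deg
        g = model.grad_torsions(ang, nuis)
        mean_fwd = ang + 0.5 * eps**2 * beta * g
        prop = _wrap_deg(mean_fwd + eps * rng.normal(size=ang.shape))
        new_lp = model._lp_torsions(prop, nuis)
        g_rev = model.grad_torsions(prop, nuis)
        mean_rev = prop + 0.5 * eps**2 * beta * g_rev
        log_q_fwd = -_angdiff2(prop, mean_fwd) / (2 * eps**2)
        log_q_rev = -_angdiff2(ang, mean_rev) / (2 * eps**2)
        log_alpha = beta * (new_lp - cur_lp) + log_q_rev - log_q_fwd
    if np.log(rng.random()) < min(0.0, log_alpha):
        state.conformer = TorsionConformer(state.conformer.sequence, prop)
        return state, True
    return state, False


def _wrap_deg(x):
    return -((-np.asarray(x) + 180.0) % 360.0 - 180.0)


def _angdiff2(a, b):
    d = ((np.asarray(a) - np.asarray(b) + 180.0) % 360.0) - 180.0
    return float(np.sum(d * d))


def exchange_attempt(state_i: PosteriorState, state_j: PosteriorState,
                     beta_i: float, beta_j: float, rng):
    """Attempt a replica swap; returns (state_i, state_j, swapped).

    Acceptance: min(1, exp((beta_i - beta_j) * (U_i - U_j))) with
    U = -log_posterior evaluated at beta = 1.  A swap exchanges the full
    states (conformer and nuisances) atomically.
    """
    u_i = -state_i.log_posterior
    u_j = -state_j.log_posterior
    log_alpha = (beta_i - beta_j) * (u_i - u_j)
    if np.log(rng.random()) < min(0.0, log_alpha):
        return state_j, state_i, True
    return state_i, state_j, False


@dataclass
class RexmcConfig:
    """Replica-exchange run parameters (desk-scale defaults)."""

    n_replicas: int = 4
    t_min: float = 300.0
    t_max: float = 400.0
    total_steps: int = 200_000
    exchange_interval: int = 100   # steps between exchange attempts
    gibbs_interval: int = 100      # steps between nuisance Gibbs sweeps
    width_deg: float = 8.0
    p_collective: float = 0.2      # collective-move probability per segment
    mala_eps_deg: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.total_steps % self.exchange_interval:
            raise ValueError("exchange_interval must divide total_steps")


@dataclass
class Trace:
    """Recorded replica-exchange history.

    ``steps[k]`` is the MC-step count at record k; ``log_posteriors`` has
    one row per record and one column per replica; ``states_cold`` are
    snapshots of the T = 300 K chain at each record.
    """

    steps: np.ndarray
    log_posteriors: np.ndarray
    states_cold: list
    exchange_attempts: np.ndarray  # per adjacent pair
    exchange_accepts: np.ndarray
    record_interval: int
    config: RexmcConfig

    def exchange_rates(self):
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.exchange_accepts / self.exchange_attempts


def _derived_seed(*key) -> int:
    return int(np.random.SeedSequence(key).generate_state(1)[0] % (2**31 - 1))


def run_rexmc(seed_conformer: TorsionConformer, restraints,
              config: RexmcConfig | None = None,
              hyper: Hyper | None = None,
              nuisance_init: NuisanceState | None = None) -> Trace:
    """Replica-exchange refinement from an annealed seed conformer.

    All replicas start from the seed; per-replica random streams are
    derived from the master seed and the replica index, so results for the
    T = 300 K chain are reproducible for a given seed.  Snapshots are
    recorded from the T = 300 K chain at every exchange boundary.
    """
    config = config or RexmcConfig()
    if hyper is None:
        # center the calibration prior on the auto-calibration constant
        from .noe_restraints import auto_calibration_constant

        intens = [r.intensity for r in restraints if r.intensity > 0]
        hyper = Hyper(mu0=float(np.log(auto_calibration_constant(intens))))
    model = StructuralModel(seed_conformer.sequence, restraints, hyper)
    ladder = build_ladder(config.n_replicas, config.t_min, config.t_max)
    betas = ladder.betas
    ns = len(model.spectrum_ids)
    if nuisance_init is None:
        nuisance_init = NuisanceState(model.spectrum_ids,
                                      np.full(ns, hyper.mu0),
                                      np.full(ns, 0.5))
    states = []
    for k in range(len(ladder)):
        st = PosteriorState(
            TorsionConformer(seed_conformer.sequence,
                             seed_conformer.angles.copy()),
            nuisance_init.copy())
        model.log_posterior(st)
        states.append(st)

    n_segments = config.total_steps // config.exchange_interval
    step_cfg = StepConfig(config.width_deg, config.mala_eps_deg,
                          config.p_collective)
    steps, lps, cold = [], [], []
    ex_att = np.zeros(max(len(ladder) - 1, 1))
    ex_acc = np.zeros(max(len(ladder) - 1, 1))

    for seg in range(n_segments):
        for k, st in enumerate(states):
            model.segment(st, betas[k], config.exchange_interval,
                          np.radians(config.width_deg),
                          _derived_seed(config.seed, k, seg))
            rng_m = np.random.default_rng(_derived_seed(
                config.seed, 777_000 + k, seg))
            if rng_m.random() < config.p_collective:
                hybrid_move(st, model, rng_m, step_cfg, beta=betas[k],
                            kind="collective")
            # conjugate nuisance updates (tempered)
            rng_g = np.random.default_rng(_derived_seed(
                config.seed, 888_000 + k, seg))
            for s in range(ns):
                model.gibbs_c(st, s, rng_g, beta=betas[k])
                model.gibbs_sigma(st, s, rng_g, beta=betas[k])
            model.log_posterior(st)
        rng_x = np.random.default_rng(_derived_seed(config.seed,
                                                    999_000, seg))
        for k in range(len(ladder) - 1):
            ex_att[k] += 1
            si, sj, swapped = exchange_attempt(states[k], states[k + 1],
                                               betas[k], betas[k + 1], rng_x)
            states[k], states[k + 1] = si, sj
            if swapped:
                ex_acc[k] += 1
        step = (seg + 1) * config.exchange_interval
        steps.append(step)
        lps.append([st.log_posterior for st in states])
        cold.append(states[0].copy())

    return Trace(np.array(steps), np.array(lps), cold,
                 ex_att, ex_acc, config.exchange_interval, config)


def burn_and_thin(trace: Trace, burn: int, stride: int):
    """Thin the cold-chain records: keep steps > burn at every ``stride``.

    With records every ``record_interval`` steps and ``stride`` a multiple
    of it, the result holds floor((total - burn)/stride) states.
    """
    if stride % trace.record_interval:
        raise ValueError(
            f"stride {stride} must be a multiple of the record interval "
            f"{trace.record_interval}")
    total = int(trace.steps[-1]) if len(trace.steps) else 0
    if burn >= total:
        warnings.warn("burn-in >= total steps: empty ensemble")
        return []
    keep = [st for step, st in zip(trace.steps, trace.states_cold)
            if step > burn and (step - burn) % stride == 0]
    return keep


def run_rexmc_scalar(logpost, x0: float, config: RexmcConfig,
                     width: float = 1.0):
    """Replica-exchange Metropolis sampling of a scalar analytic density.

    The same scheme as :func:`run_rexmc` (tempered random-walk segments,
    adjacent-pair exchanges, cold-chain recording) applied to a
    user-supplied ``logpost`` callable on the real line; used to validate
    the sampler against closed-form posteriors.  Returns the cold-chain
    samples, one per Monte Carlo step.
    """
    betas = build_ladder(config.n_replicas, config.t_min,
                         config.t_max).betas
    xs = np.full(len(betas), float(x0))
    lps = np.array([logpost(x) for x in xs])
    n_segments = config.total_steps // config.exchange_interval
    samples = np.empty(config.total_steps)
    pos = 0
    for seg in range(n_segments):
        for k in range(len(betas)):
            rng = np.random.default_rng(_derived_seed(config.seed, k, seg))
            x, lp = xs[k], lps[k]
            for _ in range(config.exchange_interval):
                prop = x + width * rng.normal()
                lp_prop = logpost(prop)
                if np.log(rng.random()) < betas[k] * (lp_prop - lp):
                    x, lp = prop, lp_prop
                if k == 0:
                    samples[pos] = x
                    pos += 1
            xs[k], lps[k] = x, lp
        rng_x = np.random.default_rng(_derived_seed(config.seed,
                                                    999_000, seg))
        for k in range(len(betas) - 1):
            log_alpha = (betas[k] - betas[k + 1]) * (-lps[k] - -lps[k + 1])
            if np.log(rng_x.random()) < min(0.0, log_alpha):
                xs[k], xs[k + 1] = xs[k + 1], xs[k]
                lps[k], lps[k + 1] = lps[k + 1], lps[k]
    return samples


def map_state(ensemble) -> PosteriorState:
    """Maximum a posteriori member; ties broken by lowest index."""
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    best = 0
    for k in range(1, len(ensemble)):
        if ensemble[k].log_posterior > ensemble[best].log_posterior:
            best = k
    return ensemble[best]
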