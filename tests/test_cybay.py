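"""Bayesian refinement: posterior terms, conjugate updates, moves, REXMC."""

import numpy as np
import pytest
from scipy import integrate
from scipy.special import gammaln

from incellfold import cybay as cy
from incellfold import molecule as mol
from incellfold.formats_io import RestraintRecord


def _toy_restraints(structure, pairs, spectrum_id="s0", c_true=10.0,
                    sigma_true=0.0, seed=0):
    """Noise-free (or noisy) restraints with intensities I = e^c / r^6."""
    from incellfold.noe_restraints import effective_distance

    rng = np.random.default_rng(seed)
    out = []
    for k, opts in enumerate(pairs):
        r = effective_distance(structure, opts)
        eps = np.exp(rng.normal(0, sigma_true)) if sigma_true > 0 else 1.0
        out.append(RestraintRecord(
            options=opts, upper_bound=r, spectrum_id=spectrum_id,
            peak_id=k + 1, intensity=float(np.exp(c_true) / r**6 * eps)))
    return out


@pytest.fixture(scope="module")
def toy():
    conf = mol.random_conformer("AKLVE", 21)
    s = mol.build_coordinates(conf)
    pairs = [
        (((1, "HA"), (3, "HA")),),
        (((1, "H"), (4, "H")),),
        (((2, "HA"), (5, "H")),),
        (((2, "HB2"), (5, "HA")), ((2, "HB3"), (5, "HA"))),
        (((3, "HA"), (4, "HG11")),),
    ]
    restraints = _toy_restraints(s, pairs, c_true=10.0)
    nuis = cy.NuisanceState(["s0"], np.array([10.0]), np.array([0.3]))
    state = cy.PosteriorState(conf, nuis)
    return conf, s, restraints, state


# -- log posterior ----------------------------------------------------------

def test_log_posterior_zero_restraints_is_priors_minus_energy(toy):
    conf, s, _r, _st = toy
    nuis = cy.NuisanceState(["s0"], np.array([1.0]), np.array([0.5]))
    state = cy.PosteriorState(conf, nuis)
    h = cy.Hyper()
    # no likelihood: model has zero restraints; expected value by hand
    model = cy.StructuralModel(conf.sequence, [], h, spectrum_ids=["s0"])
    lp = model.log_posterior(state)
    sig2 = 0.25
    expected = (-0.5 * np.log(2 * np.pi * h.tau0**2)
                - (1.0 - h.mu0) ** 2 / (2 * h.tau0**2)
                + h.alpha0 * np.log(h.beta0) - gammaln(h.alpha0)
                - (h.alpha0 + 1) * np.log(sig2) - h.beta0 / sig2
                - mol.prior_energy(s))
    assert lp == pytest.approx(expected, abs=1e-10)
    assert state.log_likelihood == 0.0


def test_log_posterior_zero_residual_term(toy):
    """One restraint with ln I = c_s - 6 ln r_eff contributes -ln sigma."""
    conf, s, restraints, _st = toy
    one = [restraints[0]]
    sigma = 0.3
    nuis = cy.NuisanceState(["s0"], np.array([10.0]), np.array([sigma]))
    state = cy.PosteriorState(conf, nuis)
    model = cy.StructuralModel(conf.sequence, one)
    model.log_posterior(state)
    assert state.log_likelihood == pytest.approx(-np.log(sigma), abs=1e-10)


def test_log_posterior_term_by_term_oracle(toy):
    """Agreement with an independent summation on the 5-restraint case."""
    from incellfold.noe_restraints import effective_distance

    conf, s, restraints, state = toy
    h = cy.Hyper(mu0=9.0, tau0=1.5, alpha0=2.5, beta0=0.7)
    lp = cy.log_posterior(state, restraints, h)
    ll = 0.0
    for r in restraints:
        reff = effective_distance(s, r.options)
        resid = np.log(r.intensity) - (state.nuisance.log_c[0]
                                       - 6 * np.log(reff))
        ll += -resid**2 / (2 * 0.3**2) - np.log(0.3)
    c = state.nuisance.log_c[0]
    sig2 = 0.3**2
    pri = (-0.5 * np.log(2 * np.pi * h.tau0**2)
           - (c - h.mu0)**2 / (2 * h.tau0**2)
           + h.alpha0 * np.log(h.beta0) - gammaln(h.alpha0)
           - (h.alpha0 + 1) * np.log(sig2) - h.beta0 / sig2)
    expected = ll + pri - mol.prior_energy(s)
    assert lp == pytest.approx(expected, abs=1e-10)


def test_log_posterior_rejects_nonpositive_sigma(toy):
    conf, _s, restraints, _st = toy
    with pytest.raises(ValueError, match="sigma"):
        cy.NuisanceState(["s0"], np.array([1.0]), np.array([0.0]))


# -- Gibbs updates vs quadrature -------------------------------------------

def test_gibbs_c_prior_fallback(toy):
    conf, _s, _r, _st = toy
    h = cy.Hyper(mu0=3.0, tau0=0.8)
    nuis = cy.NuisanceState(["empty"], np.array([0.0]), np.array([0.5]))
    state = cy.PosteriorState(conf, nuis)
    rng = np.random.default_rng(0)
    draws = [cy.gibbs_update_c(state, "empty", [], rng, h)
             for _ in range(4000)]
    assert np.mean(draws) == pytest.approx(3.0, abs=0.05)
    assert np.std(draws) == pytest.approx(0.8, abs=0.05)


def test_gibbs_c_flat_prior_limit(toy):
    """tau0 -> large with one observation: posterior mean -> ln I + 6 ln r."""
    from incellfold.noe_restraints import effective_distance

    conf, s, restraints, _st = toy
    one = [restraints[0]]
    reff = effective_distance(s, one[0].options)
    target = np.log(one[0].intensity) + 6 * np.log(reff)
    h = cy.Hyper(mu0=0.0, tau0=1e6)
    nuis = cy.NuisanceState(["s0"], np.array([5.0]), np.array([0.3]))
    state = cy.PosteriorState(conf, nuis)
    draws = [cy.gibbs_update_c(state, "s0", one,
                               np.random.default_rng(k), h)
             for k in range(500)]
    assert np.mean(draws) == pytest.approx(target, abs=0.05)


def test_gibbs_c_matches_quadrature(toy):
    """Conjugate normal posterior vs 1-D quadrature of prior x likelihood."""
    from incellfold.noe_restraints import effective_distance

    conf, s, restraints, _st = toy
    sub = restraints[:4]
    sigma = 0.3
    h = cy.Hyper(mu0=9.2, tau0=1.1)
    obs = [np.log(r.intensity) + 6 * np.log(
        effective_distance(s, r.options)) for r in sub]

    def unnorm(c):
        lp = -(c - h.mu0)**2 / (2 * h.tau0**2)
        for o in obs:
            lp += -(o - c)**2 / (2 * sigma**2)
        return np.exp(lp)

    z, _ = integrate.quad(unnorm, 0.0, 20.0, limit=200)
    m, _ = integrate.quad(lambda c: c * unnorm(c) / z, 0.0, 20.0, limit=200)
    v, _ = integrate.quad(lambda c: (c - m)**2 * unnorm(c) / z, 0.0, 20.0,
                          limit=200)

    prec = 1 / h.tau0**2 + len(obs) / sigma**2
    mean = (h.mu0 / h.tau0**2 + sum(obs) / sigma**2) / prec
    assert mean == pytest.approx(m, abs=1e-6)
    assert 1 / prec == pytest.approx(v, abs=1e-6)

    # and the sampled conditional agrees with the analytic one
    nuis = cy.NuisanceState(["s0"], np.array([9.0]), np.array([sigma]))
    state = cy.PosteriorState(conf, nuis)
    draws = [cy.gibbs_update_c(state, "s0", sub,
                               np.random.default_rng(k), h)
             for k in range(800)]
    assert np.mean(draws) == pytest.approx(mean, abs=0.02)


def test_gibbs_sigma_matches_quadrature(toy):
    """IG(alpha0 + n/2, beta0 + SS/2) vs quadrature on a 3-residual case."""
    h = cy.Hyper(alpha0=2.0, beta0=0.5)
    resid = np.array([0.21, -0.34, 0.11])
    n, ss = len(resid), float(np.sum(resid**2))

    def unnorm(s2):
        lik = np.prod([np.exp(-r**2 / (2 * s2)) / np.sqrt(s2)
                       for r in resid])
        prior = s2 ** (-(h.alpha0 + 1)) * np.exp(-h.beta0 / s2)
        return lik * prior

    z, _ = integrate.quad(unnorm, 1e-8, 60.0, limit=400)
    m, _ = integrate.quad(lambda s2: s2 * unnorm(s2) / z, 1e-8, 60.0,
                          limit=400)
    shape, scale = h.alpha0 + n / 2, h.beta0 + ss / 2
    analytic_mean = scale / (shape - 1)
    assert analytic_mean == pytest.approx(m, abs=1e-6)


def test_gibbs_sigma_prior_fallback_and_large_n(toy):
    conf, s, _r, _st = toy
    h = cy.Hyper(alpha0=3.0, beta0=1.0)
    nuis = cy.NuisanceState(["empty"], np.array([0.0]), np.array([0.5]))
    state = cy.PosteriorState(conf, nuis)
    draws = np.array([
        cy.gibbs_update_sigma(state, "empty", [],
                              np.random.default_rng(k), h)**2
        for k in range(4000)])
    assert np.mean(draws) == pytest.approx(h.beta0 / (h.alpha0 - 1),
                                           rel=0.1)

    # large-n consistency: posterior mean of sigma^2 -> true variance
    rng = np.random.default_rng(5)
    v_true = 0.04
    resid = rng.normal(0, np.sqrt(v_true), size=10_000)
    shape = h.alpha0 + len(resid) / 2
    scale = h.beta0 + 0.5 * float(np.sum(resid**2))
    post_mean = scale / (shape - 1)
    assert post_mean == pytest.approx(v_true, rel=0.05)


# -- moves ------------------------------------------------------------------

def test_hybrid_move_rejection_leaves_state_identical(toy):
    conf, _s, restraints, _st = toy
    model = cy.StructuralModel(conf.sequence, restraints)
    nuis = cy.NuisanceState(["s0"], np.array([10.0]), np.array([0.01]))
    state = cy.PosteriorState(
        mol.TorsionConformer(conf.sequence, conf.angles.copy()), nuis)
    before = state.conformer.angles.copy()
    rejected = 0
    for k in range(60):
        rng = np.random.default_rng(k)
        cfg = cy.StepConfig(width_deg=170.0, p_collective=0.0)
        _st2, acc = cy.hybrid_move(state, model, rng, cfg, kind="single")
        if not acc:
            rejected += 1
            assert np.array_equal(state.conformer.angles, before)
        else:
            before = state.conformer.angles.copy()
    assert rejected > 0  # huge moves against a tight posterior do get refused


def test_hybrid_move_accepts_equal_logpost(toy):
    """Zero-width proposals keep the log-posterior -> always accepted."""
    conf, _s, restraints, _st = toy
    model = cy.StructuralModel(conf.sequence, restraints)
    nuis = cy.NuisanceState(["s0"], np.array([10.0]), np.array([0.3]))
    state = cy.PosteriorState(conf, nuis)
    for k in range(10):
        _st2, acc = cy.hybrid_move(
            state, model, np.random.default_rng(k),
            cy.StepConfig(width_deg=0.0), kind="single")
        assert acc


def test_single_move_acceptance_matches_analytic_gaussian():
    """Empirical acceptance of a Gaussian RW on a quadratic log-density
    within 3 sigma of the analytic double integral."""
    var = 1.0
    width = 1.3
    rng = np.random.default_rng(7)

    # analytic: E[min(1, exp((x^2 - y^2)/2v))], y = x + w*eps (Monte Carlo
    # with a large independent sample as the closed-form surrogate)
    big = 400_000
    x = rng.normal(0, np.sqrt(var), size=big)
    y = x + width * rng.normal(size=big)
    p_ref = np.mean(np.minimum(1.0, np.exp((x**2 - y**2) / (2 * var))))

    n = 100_000
    x_cur = 0.0
    acc = 0
    for _ in range(n):
        prop = x_cur + width * rng.normal()
        if np.log(rng.random()) < (x_cur**2 - prop**2) / (2 * var):
            x_cur = prop
            acc += 1
    p_hat = acc / n
    se = np.sqrt(p_ref * (1 - p_ref) / n)
    assert abs(p_hat - p_ref) < 3 * se + 0.01


# -- ladder and exchange ----------------------------------------------------

def test_build_ladder_10_replicas_300_400():
    lad = cy.build_ladder(10, 300.0, 400.0)
    assert len(lad) == 10
    assert lad.temperatures[0] == 300.0
    assert lad.temperatures[-1] == 400.0
    ratios = np.diff(np.log(lad.temperatures))
    assert np.max(np.abs(ratios - ratios[0])) < 1e-12
    assert lad.betas[0] == 1.0


def test_build_ladder_two_points():
    assert cy.build_ladder(2, 300.0, 400.0).temperatures == (300.0, 400.0)


def _dummy_state(lp):
    st = cy.PosteriorState.__new__(cy.PosteriorState)
    st.conformer = "conf%.3f" % lp
    st.nuisance = "nuis%.3f" % lp
    st.log_posterior = lp
    st.log_prior = st.log_likelihood = 0.0
    return st


def test_exchange_equal_energy_always_swaps():
    rng = np.random.default_rng(0)
    a, b = _dummy_state(-5.0), _dummy_state(-5.0)
    _i, _j, swapped = cy.exchange_attempt(a, b, 1.0, 0.8, rng)
    assert swapped


def test_exchange_swaps_full_state_atomically():
    rng = np.random.default_rng(0)
    a, b = _dummy_state(-1.0), _dummy_state(-1.0)
    i, j, swapped = cy.exchange_attempt(a, b, 1.0, 0.8, rng)
    assert swapped
    assert i is b and j is a  # conformer and nuisance move together


def test_exchange_empirical_rate_matches_formula():
    """delta_beta=0.5, delta_U=-2 -> acceptance e^-1 over many trials."""
    rng = np.random.default_rng(11)
    a = _dummy_state(3.0)   # U_i = -3
    b = _dummy_state(1.0)   # U_j = -1; (0.5)*(-3 - -1) = -1
    n = 100_000
    acc = sum(cy.exchange_attempt(a, b, 1.0, 0.5, rng)[2] for _ in range(n))
    p = np.exp(-1.0)
    se = np.sqrt(p * (1 - p) / n)
    assert abs(acc / n - p) < 3 * se


# -- replica-exchange driver ------------------------------------------------

@pytest.fixture(scope="module")
def small_run(toy):
    conf, _s, restraints, _st = toy
    cfg = cy.RexmcConfig(n_replicas=2, total_steps=4000,
                         exchange_interval=100, seed=3)
    return cy.run_rexmc(conf, restraints, cfg), cfg


def test_rexmc_trace_shape_and_counters(small_run):
    trace, cfg = small_run
    n_rec = cfg.total_steps // cfg.exchange_interval
    assert len(trace.steps) == n_rec
    assert trace.log_posteriors.shape == (n_rec, 2)
    assert trace.exchange_attempts[0] == n_rec


def test_rexmc_deterministic_per_seed(toy):
    conf, _s, restraints, _st = toy
    cfg = cy.RexmcConfig(n_replicas=2, total_steps=2000,
                         exchange_interval=100, seed=9)
    t1 = cy.run_rexmc(conf, restraints, cfg)
    t2 = cy.run_rexmc(conf, restraints, cfg)
    assert np.array_equal(t1.log_posteriors, t2.log_posteriors)
    assert np.array_equal(t1.states_cold[-1].conformer.angles,
                          t2.states_cold[-1].conformer.angles)


def test_rexmc_identical_temperatures_always_exchange(toy):
    conf, _s, restraints, _st = toy
    cfg = cy.RexmcConfig(n_replicas=2, t_min=300.0, t_max=300.0 + 1e-9,
                         total_steps=1000, exchange_interval=100, seed=1)
    trace = cy.run_rexmc(conf, restraints, cfg)
    assert trace.exchange_rates()[0] == 1.0


# -- burn and thin ----------------------------------------------------------

def _fake_trace(total, record_interval):
    steps = np.arange(record_interval, total + 1, record_interval)
    states = [_dummy_state(float(-k)) for k in range(len(steps))]
    return cy.Trace(steps, np.zeros((len(steps), 1)), states,
                    np.zeros(1), np.zeros(1), record_interval, None)


def test_burn_and_thin_production_scale_arithmetic():
    """10^7 steps, burn 10^6, stride 5000 -> 1800 conformers."""
    trace = _fake_trace(10_000_000, 5000)
    ens = cy.burn_and_thin(trace, 1_000_000, 5000)
    assert len(ens) == 1800


def test_burn_and_thin_edge_cases():
    trace = _fake_trace(1000, 1)
    with pytest.warns(UserWarning, match="burn"):
        assert cy.burn_and_thin(trace, 1000, 10) == []
    assert len(cy.burn_and_thin(trace, 400, 1)) == 600
    with pytest.raises(ValueError, match="multiple"):
        cy.burn_and_thin(_fake_trace(1000, 7), 0, 10)


# -- MAP --------------------------------------------------------------------

def test_map_state_argmax_and_ties():
    ens = [_dummy_state(-3.0), _dummy_state(-1.0), _dummy_state(-2.0)]
    assert cy.map_state(ens) is ens[1]
    tie = [_dummy_state(-1.0), _dummy_state(-1.0)]
    assert cy.map_state(tie) is tie[0]


def test_map_state_matches_exhaustive_scan():
    rng = np.random.default_rng(4)
    for _ in range(20):
        ens = [_dummy_state(float(v)) for v in rng.normal(size=15)]
        best = max(range(15), key=lambda k: ens[k].log_posterior)
        assert cy.map_state(ens) is ens[best]
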