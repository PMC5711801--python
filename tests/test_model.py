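"""Design coding, HDI, relevance rule, diagnostics and sampler correctness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import oscphase as op
from oscphase import model
from oscphase.factors import EFFECT_NAMES
from conftest import TEST_PROFILE, outcomes_from_generator, tiny_config


def outcome_row(instruction, mirror, posture, speed, participant=1, correct=1):
    return {
        "participant": participant,
        "instruction": instruction,
        "mirror": mirror,
        "posture": posture,
        "speed": speed,
        "correct": correct,
    }


class TestBuildDesign:
    def test_all_positive_cell(self):
        df = pd.DataFrame(
            [
                outcome_row("symmetrical", "non-mirrored", "same", "fast", 1),
                outcome_row("parallel", "mirrored", "different", "slow", 2),
            ]
        )
        X, y, part = op.build_design(df)
        assert X[0].tolist() == [1.0] * 16

    def test_all_negative_mains_sign_products(self):
        df = pd.DataFrame(
            [
                outcome_row("parallel", "mirrored", "different", "slow", 1),
                outcome_row("symmetrical", "non-mirrored", "same", "fast", 2),
            ]
        )
        X, _, _ = op.build_design(df)
        row = dict(zip(EFFECT_NAMES, X[0]))
        for name, v in row.items():
            if name == "intercept":
                assert v == 1
            else:
                order = len(name.split("_"))
                assert v == (-1.0) ** order

    def test_balanced_table_has_orthogonal_effect_columns(self):
        rows = []
        for i, cell in enumerate(op.synth.condition_grid(tiny_config())):
            for speed in ("slow", "fast"):
                rows.append(
                    outcome_row(
                        cell.instruction, cell.mirror, cell.posture_pooled,
                        speed, cell.participant,
                    )
                )
        X, _, _ = op.build_design(pd.DataFrame(rows))
        G = X.T @ X
        off = G - np.diag(np.diag(G))
        assert np.allclose(off, 0.0)

    def test_unknown_level_rejected(self):
        df = pd.DataFrame(
            [
                outcome_row("symmetrical", "non-mirrored", "same", "warp", 1),
                outcome_row("parallel", "mirrored", "different", "slow", 2),
            ]
        )
        with pytest.raises(ValueError, match="warp"):
            op.build_design(df)

    def test_requires_two_participants(self):
        df = pd.DataFrame([outcome_row("parallel", "mirrored", "same", "slow", 1)])
        with pytest.raises(ValueError, match="participants"):
            op.build_design(df)


class TestHdi:
    def test_point_mass(self):
        assert op.hdi(np.full(500, 3.25)) == (3.25, 3.25)

    def test_standard_normal_quantiles(self):
        rng = np.random.default_rng(0)
        lo, hi = op.hdi(rng.standard_normal(1_000_000))
        assert lo == pytest.approx(-1.96, abs=0.02)
        assert hi == pytest.approx(1.96, abs=0.02)

    def test_exponential_is_left_anchored_and_matches_brute_force(self):
        rng = np.random.default_rng(1)
        draws = rng.exponential(1.0, 10_000)
        lo, hi = op.hdi(draws)
        assert lo < 0.01
        # brute-force shortest-window scan over all sorted windows
        s = np.sort(draws)
        m = int(np.ceil(0.95 * len(s)))
        widths = s[m - 1 :] - s[: len(s) - m + 1]
        i = int(np.argmin(widths))
        assert (lo, hi) == (s[i], s[i + m - 1])
        # shorter than the equal-tailed interval
        eq = np.quantile(draws, [0.025, 0.975])
        assert hi - lo < eq[1] - eq[0]

    def test_requires_enough_draws(self):
        with pytest.raises(ValueError, match="100"):
            op.hdi(np.arange(10))


class TestDecideRelevance:
    def test_interval_above_zero_contributes(self):
        rng = np.random.default_rng(2)
        assert op.decide_relevance(rng.normal(0.82, 0.015, 5000))

    def test_interval_spanning_zero_does_not(self):
        rng = np.random.default_rng(3)
        assert not op.decide_relevance(rng.normal(0.02, 0.015, 5000))

    def test_boundary_at_zero_reads_as_spanning(self):
        draws = np.concatenate([np.zeros(500), -np.linspace(0.001, 0.06, 4500)])
        lo, hi = op.hdi(draws)
        assert hi == 0.0
        assert not op.decide_relevance(draws)


class TestDiagnostics:
    def test_independent_draws_have_full_ess(self):
        rng = np.random.default_rng(4)
        draws = rng.standard_normal((2, 4000, 1))
        d = op.diagnostics(draws)
        assert d.ess.iloc[0] == pytest.approx(8000, rel=0.10)

    def test_autocorrelated_chain_has_small_ess(self):
        # AR(1) with phi = 0.95: ESS/n ~ (1-phi)/(1+phi) ~ 1/39
        rng = np.random.default_rng(5)
        n, phi = 8000, 0.95
        x = np.empty((2, n))
        for c in range(2):
            e = rng.standard_normal(n)
            x[c, 0] = e[0]
            for i in range(1, n):
                x[c, i] = phi * x[c, i - 1] + e[i] * np.sqrt(1 - phi**2)
        d = op.diagnostics(x[:, :, None])
        assert d.ess.iloc[0] < 0.1 * 2 * n

    def test_same_distribution_chains_converge(self):
        rng = np.random.default_rng(6)
        d = op.diagnostics(rng.standard_normal((4, 2000, 3)))
        assert (d.shrink_factor < 1.05).all()
        assert d.converged

    def test_single_chain_shrink_factor_missing(self):
        rng = np.random.default_rng(7)
        d = op.diagnostics(rng.standard_normal((1, 2000, 2)))
        assert d.shrink_factor.isna().all()


def reference_metropolis(Xc, succ, tot, cell_part, J, n_iter, seed, prior):
    """Independent reference sampler: naive scalar-loop random-walk
    Metropolis over every coordinate, with hyperprior draws through scipy's
    generalized-inverse-Gaussian (no shared code with the fast path)."""
    rng = np.random.default_rng(seed)
    P = Xc.shape[1]
    beta = np.zeros(P)
    u = np.zeros(J)
    tau_b = np.ones(P)
    tau_u = 1.0

    def loglik(b, uu):
        eta = Xc @ b + uu[cell_part]
        return float(np.sum(succ * eta - tot * np.log1p(np.exp(eta))))

    ll = loglik(beta, u)
    keep = []
    for it in range(n_iter):
        for k in range(P):
            prop = beta.copy()
            prop[k] += rng.normal(0, 0.4)
            llp = loglik(prop, u)
            dprior = -0.5 * tau_b[k] * (prop[k] ** 2 - beta[k] ** 2)
            if np.log(rng.random()) < llp - ll + dprior:
                beta, ll = prop, llp
        for j in range(J):
            prop = u.copy()
            prop[j] += rng.normal(0, 0.4)
            llp = loglik(beta, prop)
            dprior = -0.5 * tau_u * (prop[j] ** 2 - u[j] ** 2)
            if np.log(rng.random()) < llp - ll + dprior:
                u, ll = prop, llp
        # recentering move (priors only; likelihood invariant)
        delta = rng.normal(0, 0.3)
        dlp = -0.5 * tau_b[0] * ((beta[0] + delta) ** 2 - beta[0] ** 2)
        dlp += -0.5 * tau_u * (((u - delta) ** 2).sum() - (u**2).sum())
        if np.log(rng.random()) < dlp:
            beta = beta.copy()
            beta[0] += delta
            u = u - delta
        p_gig = 0.5 - prior.shape
        for k in range(P):
            psi = max(beta[k] ** 2, 1e-12)
            tau_b[k] = stats.geninvgauss.rvs(
                p_gig, np.sqrt(2 * prior.scale * psi),
                scale=np.sqrt(2 * prior.scale / psi), random_state=rng,
            )
        psi = max((u**2).sum(), 1e-12)
        tau_u = stats.geninvgauss.rvs(
            J / 2 - prior.shape, np.sqrt(2 * prior.scale * psi),
            scale=np.sqrt(2 * prior.scale / psi), random_state=rng,
        )
        if it >= n_iter // 4:
            keep.append(beta.copy())
    return np.array(keep)


class TestFitModel:
    def test_small_instance_matches_reference_sampler(self):
        # 2 participants, ~200 cycles: posterior means from the package
        # sampler vs an independently coded long-run Metropolis reference
        cfg = tiny_config(n_participants=2, seed=31)
        out = outcomes_from_generator(cfg)
        out = out.groupby(
            ["participant", "instruction", "mirror", "posture", "speed"],
            observed=True,
        ).head(7).reset_index(drop=True)
        X, y, part = op.build_design(out)
        post, diag = op.fit_model(
            X, y, part, settings=model.McmcSettings(chains=4, burn_in=1000,
                                                    draws=4000, thin=1),
            seed=3,
        )
        Xc, succ, tot, cell_part, pid = model._aggregate_cells(X, y, part)
        order = np.argsort(cell_part, kind="stable")
        ref = reference_metropolis(
            Xc[order], succ[order], tot[order], cell_part[order], len(pid),
            n_iter=6000, seed=17, prior=model.PriorSpec(),
        )
        # with ~200 cycles over 32 cells the beta posterior is diffuse and
        # heavy-tailed (prior-dominated): raw weight means carry large
        # Monte-Carlo error in any finite chain, so compare the bounded
        # posterior cell probabilities, whose MC error here is ~0.05
        def cell_probs(draws):
            eta = draws @ Xc[order].T
            return (1 / (1 + np.exp(-eta))).mean(axis=0)

        ours = cell_probs(post.beta_flat)
        theirs = cell_probs(ref)
        assert np.max(np.abs(ours - theirs)) < 0.08

    def test_null_data_yields_null_decisions(self):
        betas = {e: 0.0 for e in EFFECT_NAMES}
        cfg = op.SimulationConfig(
            n_participants=6, sessions=1, reps_per_condition=2,
            true_betas=betas, participant_sd=0.3, seed=21,
        )
        out = outcomes_from_generator(cfg)
        X, y, part = op.build_design(out)
        post, _ = op.fit_model(X, y, part, settings=TEST_PROFILE, seed=2)
        decisions = [
            op.decide_relevance(post.beta_flat[:, k])
            for k, e in enumerate(EFFECT_NAMES) if e != "intercept"
        ]
        # allow the nominal 5% false-exclusion rate some room
        assert sum(decisions) <= 2

    def test_single_factor_effect_recovered(self):
        betas = {e: 0.0 for e in EFFECT_NAMES}
        betas["intercept"] = 1.0
        betas["instruction"] = 0.82
        cfg = op.SimulationConfig(
            n_participants=8, sessions=1, reps_per_condition=2,
            true_betas=betas, participant_sd=0.3, seed=22,
        )
        out = outcomes_from_generator(cfg)
        X, y, part = op.build_design(out)
        post, _ = op.fit_model(X, y, part, settings=TEST_PROFILE, seed=4)
        k = EFFECT_NAMES.index("instruction")
        draws = post.beta_flat[:, k]
        assert abs(draws.mean() - 0.82) < 3 * draws.std()
        assert op.decide_relevance(draws)

    def test_label_switch_flips_signs(self):
        cfg = tiny_config(n_participants=4, seed=33, reps_per_condition=2)
        out = outcomes_from_generator(cfg)
        X, y, part = op.build_design(out)
        post_a, _ = op.fit_model(X, y, part, settings=TEST_PROFILE, seed=6)
        swapped = out.assign(
            instruction=out["instruction"].map(
                {"symmetrical": "parallel", "parallel": "symmetrical"}
            )
        )
        Xs, ys, ps = op.build_design(swapped)
        post_b, _ = op.fit_model(Xs, ys, ps, settings=TEST_PROFILE, seed=6)
        for k, name in enumerate(EFFECT_NAMES):
            sign = -1.0 if "instruction" in name.split("_") else 1.0
            a = post_a.beta_flat[:, k]
            b = post_b.beta_flat[:, k]
            tol = 4 * np.hypot(a.std(), b.std()) / np.sqrt(min(len(a), 400) / 8)
            assert a.mean() == pytest.approx(sign * b.mean(), abs=max(tol, 0.05))

    def test_posterior_concentrates_with_sample_size(self):
        sds = []
        for n_reps, n_part in ((1, 2), (2, 8)):
            cfg = tiny_config(n_participants=n_part, seed=44,
                              reps_per_condition=n_reps)
            out = outcomes_from_generator(cfg)
            X, y, part = op.build_design(out)
            post, _ = op.fit_model(X, y, part, settings=TEST_PROFILE, seed=8)
            k = EFFECT_NAMES.index("instruction")
            sds.append(post.beta_flat[:, k].std())
        assert sds[1] < sds[0]

    def test_degenerate_outcomes_warn(self):
        cfg = tiny_config(seed=55)
        out = outcomes_from_generator(cfg).assign(correct=1)
        X, y, part = op.build_design(out)
        with pytest.warns(UserWarning, match="degenerate"):
            op.fit_model(
                X, y, part,
                settings=model.McmcSettings(chains=2, burn_in=100, draws=200),
                seed=9,
            )

    def test_reproducible_under_fixed_seed(self):
        cfg = tiny_config(seed=66)
        out = outcomes_from_generator(cfg)
        X, y, part = op.build_design(out)
        s = model.McmcSettings(chains=2, burn_in=200, draws=300)
        post_a, _ = op.fit_model(X, y, part, settings=s, seed=10)
        post_b, _ = op.fit_model(X, y, part, settings=s, seed=10)
        np.testing.assert_array_equal(post_a.beta, post_b.beta)


class TestPriorRobustness:
    def test_alternative_hyperprior_keeps_decisions(self, default_fit):
        config, out, post, diag = default_fit
        X, y, part = op.build_design(out)
        post_alt, _ = op.fit_model(
            X, y, part, settings=TEST_PROFILE, seed=13,
            prior=model.ALTERNATIVE_PRIOR,
        )
        true = config.beta_vector
        for k, name in enumerate(EFFECT_NAMES):
            if abs(true[k]) >= 0.1:  # well-powered effects only
                assert op.decide_relevance(post.beta_flat[:, k])
                assert op.decide_relevance(post_alt.beta_flat[:, k])

    def test_variance_parameterization_also_fits(self):
        cfg = tiny_config(seed=77)
        out = outcomes_from_generator(cfg)
        X, y, part = op.build_design(out)
        post, diag = op.fit_model(
            X, y, part,
            settings=model.McmcSettings(chains=2, burn_in=300, draws=500),
            seed=11,
            prior=model.PriorSpec(parameterization="variance-ig"),
        )
        assert np.isfinite(post.beta_flat).all()
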