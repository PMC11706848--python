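"""Droplet classification, thresholding and Poisson quantification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from trimeth.ddpcr import (
    Channel,
    ControlFailure,
    DropletWell,
    ReactionGeometry,
    SaturatedWellError,
    Target,
    WellRole,
    classify_droplets,
    copies_per_ml_plasma,
    poisson_concentration,
    set_threshold_from_controls,
)


def _well(amplitudes, role=WellRole.sample, channel=Channel.ch1, plate="P1-MET"):
    return DropletWell(
        well_id=f"{role.value[:3]}",
        plate_id=plate,
        channel=channel,
        target=Target.C9orf50,
        role=role,
        amplitudes=np.asarray(amplitudes, dtype=float),
    )


def _neg_fixture():
    # median exactly 1000, MAD exactly 40
    return _well(np.tile([960.0, 1000.0, 1040.0], 100), role=WellRole.negative_control)


class TestThreshold:
    def test_interpolation_rule_on_fixed_clusters(self):
        """Two clean clusters at 1000/9000: cutoff lands 40% up the range."""
        pos = _well(
            np.concatenate([np.full(300, 1000.0), np.full(100, 9000.0)]),
            role=WellRole.positive_control,
        )
        thr = set_threshold_from_controls(_neg_fixture(), pos)
        assert thr.threshold == pytest.approx(1000 + 0.4 * 8000)  # 4200
        assert thr.neg_center == pytest.approx(1000.0)
        assert thr.pos_center == pytest.approx(9000.0)

    def test_unseparated_positive_control_fails_plate(self):
        """Upper cluster within 4x the negative spread is a control failure."""
        pos = _well(
            np.concatenate([np.full(300, 1000.0), np.full(100, 1100.0)]),
            role=WellRole.positive_control,
        )
        with pytest.raises(ControlFailure):
            set_threshold_from_controls(_neg_fixture(), pos)

    def test_zero_spread_negative_control(self):
        """All-identical negative amplitudes (MAD 0) still give the 40% cutoff."""
        neg = _well(np.full(500, 1000.0), role=WellRole.negative_control)
        pos = _well(
            np.concatenate([np.full(300, 1000.0), np.full(100, 9000.0)]),
            role=WellRole.positive_control,
        )
        thr = set_threshold_from_controls(neg, pos)
        assert thr.threshold == pytest.approx(4200.0)

    def test_channel_mismatch_rejected(self):
        pos = _well(
            np.concatenate([np.full(300, 1000.0), np.full(100, 9000.0)]),
            role=WellRole.positive_control,
            channel=Channel.ch2,
        )
        with pytest.raises(ValueError, match="share plate and channel"):
            set_threshold_from_controls(_neg_fixture(), pos)

    @given(scale=st.floats(min_value=0.1, max_value=50.0))
    def test_scale_equivariance(self, scale):
        """Scaling every amplitude by a common factor scales the threshold
        identically and leaves droplet classification unchanged."""
        rng = np.random.default_rng(11)
        neg_amp = rng.normal(1000, 40, 2000)
        pos_amp = np.concatenate([rng.normal(1000, 40, 1500), rng.normal(9000, 200, 500)])
        sample_amp = np.concatenate([rng.normal(1000, 40, 3000), rng.normal(9000, 200, 7)])

        def run(f):
            neg = _well(neg_amp * f, role=WellRole.negative_control)
            pos = _well(pos_amp * f, role=WellRole.positive_control)
            thr = set_threshold_from_controls(neg, pos)
            return thr.threshold, classify_droplets(_well(sample_amp * f), thr)

        t1, kn1 = run(1.0)
        t2, kn2 = run(scale)
        assert t2 == pytest.approx(t1 * scale, rel=1e-9)
        assert kn1 == kn2


class TestClassification:
    def test_counts_strictly_above_threshold(self):
        pos = _well(
            np.concatenate([np.full(300, 1000.0), np.full(100, 9000.0)]),
            role=WellRole.positive_control,
        )
        thr = set_threshold_from_controls(_neg_fixture(), pos)
        assert classify_droplets(_well([1000.0, 1050.0, 9000.0]), thr) == (1, 3)
        assert classify_droplets(_well([1000.0] * 5), thr) == (0, 5)
        # a droplet exactly at the threshold counts negative
        assert classify_droplets(_well([thr.threshold, 9000.0]), thr) == (1, 2)

    def test_plate_mismatch_rejected(self):
        pos = _well(
            np.concatenate([np.full(300, 1000.0), np.full(100, 9000.0)]),
            role=WellRole.positive_control,
        )
        thr = set_threshold_from_controls(_neg_fixture(), pos)
        other = _well([1000.0, 9000.0], plate="P2-MET")
        with pytest.raises(ValueError, match="does not match"):
            classify_droplets(other, thr)


class TestPoissonQuantification:
    def test_zero_positive_droplets(self):
        m = poisson_concentration(0, 20000)
        assert m.lam == 0.0
        assert m.conc_per_ul_reaction == 0.0
        assert m.copies_per_reaction == 0.0

    def test_known_occupancy(self):
        """k=100 of 20,000 droplets: lambda = -ln(0.995)."""
        m = poisson_concentration(100, 20000)
        assert m.lam == pytest.approx(-np.log(0.995))
        assert m.conc_per_ul_reaction == pytest.approx(5.8971, rel=1e-4)
        assert m.copies_per_reaction == pytest.approx(129.736, rel=1e-4)

    def test_saturated_well_has_no_concentration(self):
        m = poisson_concentration(15000, 15000)
        assert m.saturated
        assert np.isnan(m.copies_per_reaction)
        with pytest.raises(SaturatedWellError):
            copies_per_ml_plasma(m, ReactionGeometry())

    @pytest.mark.parametrize("k,n", [(-1, 10), (11, 10), (0, 0)])
    def test_invalid_counts_rejected(self, k, n):
        with pytest.raises(ValueError):
            poisson_concentration(k, n)

    def test_monotone_in_positive_count(self):
        lams = [poisson_concentration(k, 5000).lam for k in range(0, 4999, 100)]
        assert np.all(np.diff(lams) > 0)

    def test_estimator_matches_partitioning_oracle(self):
        """Random partitioning of M molecules into n droplets: the Poisson
        estimate of occupied-droplet counts recovers M within 2%."""
        n = 20000
        for M in (10, 100, 1000):
            rng = np.random.default_rng(M)
            est = np.empty(2000)
            for i in range(2000):
                occupied = np.unique(rng.integers(0, n, M)).size
                est[i] = -np.log1p(-occupied / n) * n
            assert abs(est.mean() / M - 1) < 0.02


class TestPlasmaScaling:
    def test_arithmetic_chain(self):
        """129.7 reaction copies from 8 of 22 uL eluate and 8 mL plasma."""
        g = ReactionGeometry(template_volume=8.0, eluate_volume=22.0, plasma_volume=8.0)
        m = poisson_concentration(100, 20000, g)
        assert copies_per_ml_plasma(m, g) == pytest.approx(129.736 * 2.75 / 8, rel=1e-4)

    def test_zero_in_zero_out(self):
        g = ReactionGeometry()
        m = poisson_concentration(0, 20000, g)
        assert copies_per_ml_plasma(m, g) == 0.0

    def test_full_eluate_identity_scaling(self):
        g = ReactionGeometry(template_volume=22.0, eluate_volume=22.0, plasma_volume=1.0)
        m = poisson_concentration(50, 20000, g)
        assert copies_per_ml_plasma(m, g) == pytest.approx(m.copies_per_reaction)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            ReactionGeometry(template_volume=25.0, eluate_volume=22.0)
        with pytest.raises(ValueError):
            ReactionGeometry(plasma_volume=0.0)


def test_simulated_wells_within_poisson_interval():
    """Round trip with the generator: for wells simulated at a known
    concentration, the binomial 95% interval around the estimate covers the
    true value for ~95% of wells."""
    from scipy.stats import beta

    from trimeth.simulate import SimulationConfig, _well_amplitudes

    cfg = SimulationConfig(seed=21)
    g = ReactionGeometry()
    true_lam = 0.004
    rng = np.random.default_rng(21)
    n = 21000
    covered = 0
    reps = 300
    for _ in range(reps):
        amp = _well_amplitudes(cfg, rng, n, true_lam)
        k = int((amp > 4200.0).sum())
        # Clopper-Pearson interval on the positive fraction -> lambda interval
        p_lo = beta.ppf(0.025, k, n - k + 1) if k > 0 else 0.0
        p_hi = beta.ppf(0.975, k + 1, n - k)
        lam_lo, lam_hi = -np.log1p(-p_lo), -np.log1p(-p_hi)
        covered += lam_lo <= true_lam <= lam_hi
    assert covered / reps >= 0.93
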