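"""Dose-survival curves, dose-to-p mappings, HRS/IRR classification."""
import numpy as np
import pytest

from radcell.dose_response import (
    DoseMapping,
    DoseResponseCurve,
    classify_phases,
    dose_response_curve,
    hrs_irr_mapping,
    p_of_dose,
    survival_fraction,
)
from radcell.model import ModelParams

BASE = ModelParams(alpha=1.0, p=0.0, c=1.0, eta=0.01, memory=1)
COMM_BASE = ModelParams(alpha=1.0, p=0.0, c=1.0, eta=0.01, beta0=10.0, memory=0)


class TestDoseMapping:
    def test_linear_example(self):
        m = DoseMapping(form="linear", p0=0.4, p1=0.55, mode="fixed_duration",
                        duration=150.0)
        assert p_of_dose(1.0, m) == pytest.approx(0.95)
        assert p_of_dose(0.0, m) == pytest.approx(0.4)
        assert p_of_dose(100.0, m) == 1.0  # clipped

    def test_saturating_limits(self):
        m = DoseMapping(form="saturating", p0=1.0, p1=0.8, mode="fixed_rate",
                        dose_rate=1.0)
        assert p_of_dose(0.0, m) == 0.0
        assert p_of_dose(1e9, m) == pytest.approx(0.8, rel=1e-6)  # plateau p1
        d = np.linspace(0, 50, 200)
        ps = [p_of_dose(x, m) for x in d]
        assert np.all(np.diff(ps) >= 0)

    @pytest.mark.parametrize("kwargs", [
        dict(form="saturating", p0=1.0, p1=1.3, mode="fixed_rate", dose_rate=1.0),
        dict(form="linear", p0=-0.1, p1=0.5, mode="fixed_duration", duration=10.0),
        dict(form="linear", p0=0.1, p1=0.5, mode="fixed_duration"),
        dict(form="weird", p0=0.1, p1=0.5, mode="fixed_rate", dose_rate=1.0),
    ])
    def test_invalid_mappings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DoseMapping(**kwargs)


class TestSurvivalFraction:
    def test_zero_dose_full_survival(self):
        frac, ln = survival_fraction(BASE, hrs_irr_mapping(), 0.0)
        assert frac == 1.0 and ln == 0.0

    def test_monotone_decreasing_in_dose(self):
        m = hrs_irr_mapping()
        doses = np.geomspace(1e-3, 0.6, 25)
        fracs = [survival_fraction(BASE, m, d)[0] for d in doses]
        assert np.all(np.diff(fracs) < 0)

    def test_modes_agree_at_matched_exposure(self):
        # same (alpha, t) pair reached through either mode gives the same
        # survival when p depends only on the cumulative dose
        alpha, t = 0.42, 6.0
        dose = alpha * t
        common = dict(form="saturating", p0=1.0, p1=0.8, dose_scale=1.0)
        m_rate = DoseMapping(mode="fixed_rate", dose_rate=alpha, **common)
        m_dur = DoseMapping(mode="fixed_duration", duration=t, **common)
        pr = ModelParams(alpha=1.0, p=0.0, c=1.0, eta=0.052, memory=1)
        f1, _ = survival_fraction(pr, m_rate, dose)
        f2, _ = survival_fraction(pr, m_dur, dose)
        assert f1 == pytest.approx(f2, rel=1e-8)

    def test_linear_and_ode_paths_agree(self):
        m = hrs_irr_mapping()
        for d in (0.01, 0.1, 0.5):
            f_ode, _ = survival_fraction(BASE, m, d, method="ode")
            f_lin, _ = survival_fraction(BASE, m, d, method="linear")
            assert f_ode == pytest.approx(f_lin, rel=1e-6)


@pytest.fixture(scope="module")
def hrs_curve():
    return dose_response_curve(BASE, hrs_irr_mapping())


class TestPhaseClassification:
    def test_memory_model_shows_signature(self, hrs_curve):
        cls = classify_phases(hrs_curve)
        assert cls.has_signature
        assert abs(cls.s_hrs) > abs(cls.s_high) > abs(cls.s_irr)

    def test_constant_p_has_no_signature(self):
        m = DoseMapping(form="linear", p0=0.4, p1=0.0, mode="fixed_duration",
                        duration=150.0, dose_scale=1.0 / 150.0)
        assert not classify_phases(dose_response_curve(BASE, m)).has_signature

    def test_communication_model_has_no_signature(self):
        curve = dose_response_curve(COMM_BASE, hrs_irr_mapping())
        assert not classify_phases(curve).has_signature

    def test_pure_exponential_has_no_signature(self):
        doses = np.geomspace(1e-3, 1.0, 60)
        lnS = -2.0 * doses
        curve = DoseResponseCurve(doses=doses, surviving_fraction=np.exp(lnS),
                                  ln_surviving_fraction=lnS)
        cls = classify_phases(curve)
        assert not cls.has_signature
        assert cls.s_hrs == pytest.approx(-2.0, rel=1e-6)
        assert cls.s_irr == pytest.approx(-2.0, rel=1e-6)
        assert cls.s_high == pytest.approx(-2.0, rel=1e-6)

    def test_phase_labels_cover_curve(self, hrs_curve):
        classify_phases(hrs_curve)
        assert len(hrs_curve.phase_labels) == hrs_curve.doses.size
        assert hrs_curve.phase_labels[0] == "HRS"
        assert hrs_curve.phase_labels[-1] == "high-dose"
        assert "IRR" in hrs_curve.phase_labels

    def test_irr_onset_coincides_with_population_saturation(self, hrs_curve):
        # at the shallowest (IRR) dose the exposure is strong enough that
        # essentially no cell remains in the susceptible pool
        from radcell.dose_response import survival_fraction as sf
        from radcell.model import integrate
        cls = classify_phases(hrs_curve)
        m = hrs_irr_mapping()
        alpha, t_exp = m.exposure(cls.d_irr)
        pr = BASE.replace(alpha=alpha, p=m.p_of_dose(cls.d_irr))
        traj = integrate(pr, (100.0, 0, 0, 0), np.linspace(0, t_exp, 20))
        x_frac = traj.x[-1] / traj.unaltered[-1]
        assert x_frac < 0.25
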