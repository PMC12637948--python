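"""Rate laws, Haldane relationship, and ODE assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cfkinetics import (
    BDHParams,
    DecompParams,
    FDHParams,
    Reaction,
    Species,
    ThermoInfo,
    assemble_rhs,
    bdh_model,
    bdh_rate,
    decomp_rate,
    fdh_model,
    fdh_rate,
    haldane_keq,
    haldane_residual,
)
from cfkinetics.model import KineticModel, model_from_dict

BENCH = FDHParams(kcat=0.18, KIA=78.14, KIQ=0.118, KMA=0.0384, KMB=0.472)

positive = st.floats(min_value=1e-3, max_value=1e3)
conc = st.floats(min_value=0.0, max_value=1e3)


class TestFDHRate:
    @pytest.mark.parametrize(
        "A,B,Q,E",
        [(0.0, 50.0, 0.1, 1.0), (1.0, 0.0, 0.0, 1.0), (1.0, 100.0, 0.0, 0.0)],
    )
    def test_vanishes_when_numerator_vanishes(self, A, B, Q, E):
        assert fdh_rate(BENCH, A, B, Q, E) == 0.0

    def test_benchmark_point_matches_scalar_oracle(self):
        # independent single-expression evaluation of the rate law
        A, B, Q, E = 1.0, 100.0, 0.0, 1.0
        expected = (60 * 0.18 * A * B * E) / (
            78.14 * 0.472 + 0.472 * A + 0.0384 * B + A * B
            + (78.14 * 0.472 / 0.118) * Q + (0.0384 / 0.118) * B * Q
        )
        assert fdh_rate(BENCH, A, B, Q, E) == pytest.approx(expected, rel=1e-12)

    def test_saturation_limit_is_kcat_times_enzyme(self):
        # A*B dominates the denominator at saturating substrate
        v = fdh_rate(BENCH, 1e9, 1e9, 0.0, 2.0)
        assert v == pytest.approx(60 * BENCH.kcat * 2.0, rel=1e-4)

    @given(A=positive, B=positive, E=positive)
    @settings(max_examples=50, deadline=None)
    def test_product_inhibition_monotone_in_Q(self, A, B, E):
        rates = [fdh_rate(BENCH, A, B, q, E) for q in np.linspace(0, 10, 11)]
        assert all(r >= 0 for r in rates)
        assert all(a >= b - 1e-15 for a, b in zip(rates, rates[1:]))

    def test_rejects_non_finite_and_negative_inputs(self):
        with pytest.raises(ValueError):
            fdh_rate(BENCH, float("nan"), 1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            fdh_rate(BENCH, -1.0, 1.0, 0.0, 1.0)

    def test_parameters_must_be_positive(self):
        with pytest.raises(ValueError):
            FDHParams(kcat=0.18, KIA=0.0, KIQ=0.118, KMA=0.0384, KMB=0.472)


class TestBDHRate:
    P0 = BDHParams(kcatf=50.0, kcatr=0.8, KMS=1.0, KMQ=0.1, KMP=10.0, KMA=1.0)

    def test_zero_concentrations_zero_rate(self):
        assert bdh_rate(self.P0, 0, 0, 0, 0, 1.0) == 0.0

    def test_numerator_balance_gives_zero(self):
        # choose P, A so kcatf*S*Q/(KMS*KMQ) == kcatr*P*A/(KMP*KMA)
        p = self.P0
        S, Q, A = 2.0, 0.3, 1.5
        P = p.kcatf * (S / p.KMS) * (Q / p.KMQ) * p.KMP * p.KMA / (p.kcatr * A)
        assert bdh_rate(p, S, Q, P, A, 1.0) == pytest.approx(0.0, abs=1e-12)

    @given(S=conc, Q=conc, P=conc, A=conc, E=positive)
    @settings(max_examples=100, deadline=None)
    def test_matches_scalar_oracle(self, S, Q, P, A, E):
        p = self.P0
        num = 60 * E * (
            p.kcatf * S * Q / (p.KMS * p.KMQ) - p.kcatr * P * A / (p.KMP * p.KMA)
        )
        den = (
            (1 + S / p.KMS) * (1 + Q / p.KMQ)
            + (1 + P / p.KMP) * (1 + A / p.KMA) - 1
        )
        expected = num / den
        assert bdh_rate(p, S, Q, P, A, E) == pytest.approx(
            expected, rel=1e-12, abs=1e-12
        )

    def test_haldane_consistent_zero_crossing_ratio(self):
        thermo = ThermoInfo(dG0=-22.5, T=310.15)
        keq = haldane_keq(thermo)
        p = self.P0
        kcatr = p.kcatf * p.KMP * p.KMA / (keq * p.KMS * p.KMQ)
        pc = BDHParams(p.kcatf, kcatr, p.KMS, p.KMQ, p.KMP, p.KMA)
        # at the zero-rate point the mass-action ratio (P*A)/(S*Q) equals Keq
        S, Q, A = 5.0, 0.2, 2.0
        P = keq * S * Q / A
        assert bdh_rate(pc, S, Q, P, A, 1.0) == pytest.approx(0.0, abs=1e-9)
        assert (P * A) / (S * Q) == pytest.approx(keq, rel=1e-10)


class TestDecompAndHaldane:
    def test_decomp_zero_and_scalar_oracle(self):
        assert decomp_rate(DecompParams(1e-3), 0.0) == 0.0
        # 3.45e-2 1/h at 1 mM is 3.45e-2 mM/h before unit conversion
        p = DecompParams.from_per_hour(3.45e-2)
        assert decomp_rate(p, 1.0) * 60.0 == pytest.approx(3.45e-2, rel=1e-12)

    def test_decomp_rejects_negative_concentration(self):
        with pytest.raises(ValueError):
            decomp_rate(DecompParams(1e-3), -0.1)

    def test_keq_identity_at_zero_free_energy(self):
        assert haldane_keq(ThermoInfo(dG0=0.0, T=310.15)) == 1.0

    def test_keq_scalar_oracle(self):
        expected = math.exp(22.5 / (0.008314 * 310.15))
        got = haldane_keq(ThermoInfo(dG0=-22.5, T=310.15))
        assert got == pytest.approx(expected, rel=1e-12)
        assert 5.5e3 < got < 7e3

    def test_keq_decreases_toward_one_with_temperature(self):
        keqs = [haldane_keq(ThermoInfo(dG0=-22.5, T=t)) for t in (300, 400, 600, 1200)]
        assert all(a > b > 1 for a, b in zip(keqs, keqs[1:]))

    def test_haldane_residual_zero_when_consistent(self):
        keq = 6159.0
        p = BDHParams(kcatf=50.0, kcatr=50.0 * 10.0 * 1.0 / (keq * 1.0 * 0.1),
                      KMS=1.0, KMQ=0.1, KMP=10.0, KMA=1.0)
        assert haldane_residual(p, keq) == pytest.approx(0.0, abs=1e-9)

    def test_haldane_residual_collapses_to_one_minus_keq(self):
        p = BDHParams(kcatf=2.0, kcatr=2.0, KMS=3.0, KMQ=3.0, KMP=3.0, KMA=3.0)
        assert haldane_residual(p, 4.0) == pytest.approx(1.0 - 4.0, rel=1e-12)

    def test_haldane_residual_doubles_with_kcatf(self):
        p1 = BDHParams(kcatf=2.0, kcatr=1.0, KMS=1.0, KMQ=1.0, KMP=1.0, KMA=1.0)
        p2 = BDHParams(kcatf=4.0, kcatr=1.0, KMS=1.0, KMQ=1.0, KMP=1.0, KMA=1.0)
        keq = 3.0
        assert haldane_residual(p2, keq) - haldane_residual(p1, keq) == pytest.approx(
            2.0, rel=1e-12
        )


class TestAssembleRhs:
    def test_zero_enzyme_zero_kdq_is_stationary(self):
        m = fdh_model({"E_fdh": 0.0, "kdq": 0.0})
        rhs = assemble_rhs(m, m.params)
        x = np.array([1.0, 100.0, 0.5, 0.0, 0.0])
        assert np.allclose(rhs(0.0, x), 0.0)

    def test_fdh_rate_vanishes_without_nad(self):
        m = fdh_model()
        rhs = assemble_rhs(m, m.params)
        x = np.zeros(5)
        x[m.index_of("B")] = 100.0
        x[m.index_of("Q")] = 0.7
        dx = rhs(0.0, x)
        assert dx[m.index_of("Q")] == pytest.approx(
            -m.params["kdq"] * 0.7, rel=1e-12
        )

    def test_bdh_stoichiometric_conservation(self):
        m = bdh_model({"kdq": 0.0})
        rhs = assemble_rhs(m, m.params)
        x = np.array([10.0, 0.4, 2.0, 1.0, 0.0])  # S, Q, P, A, X
        dx = rhs(0.0, x)
        iS, iQ, iP, iA = (m.index_of(s) for s in "SQPA")
        assert dx[iS] + dx[iP] == pytest.approx(0.0, abs=1e-14)
        assert dx[iA] + dx[iQ] == pytest.approx(0.0, abs=1e-14)


class TestModelValidation:
    def test_duplicate_roles_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            KineticModel(
                species=[Species("A", "x", "A"), Species("A2", "y", "A")],
                reactions=[],
                params={},
            )

    def test_inconsistent_stoichiometry_rejected(self):
        m = fdh_model()
        bad = Reaction(
            id="FDH",
            stoichiometry={"A": -1, "B": -1, "Q": -1, "C": +1},  # Q sign flipped
            rate_law="fdh",
            params={"kcat": "kcat", "KIA": "KIA", "KIQ": "KIQ", "KMA": "KMA",
                    "KMB": "KMB", "E": "E_fdh"},
        )
        with pytest.raises(ValueError, match="stoichiometry"):
            KineticModel(species=m.species, reactions=[bad], params=m.params)

    def test_missing_parameter_reference_rejected(self):
        m = fdh_model()
        bad = Reaction(
            id="FDH",
            stoichiometry={"A": -1, "B": -1, "Q": +1, "C": +1},
            rate_law="fdh",
            params={"kcat": "nope", "KIA": "KIA", "KIQ": "KIQ", "KMA": "KMA",
                    "KMB": "KMB", "E": "E_fdh"},
        )
        with pytest.raises(ValueError, match="parameter"):
            KineticModel(species=m.species, reactions=[bad], params=m.params)

    def test_unknown_rate_law_rejected(self):
        m = fdh_model()
        bad = Reaction(id="r", stoichiometry={"Q": -1, "X": 1}, rate_law="magic")
        with pytest.raises(ValueError, match="unknown rate law"):
            KineticModel(species=m.species, reactions=[bad], params=m.params)

    def test_model_from_dict_round_trip(self):
        m = fdh_model()
        cfg = {
            "species": [{"id": s.id, "name": s.name, "role": s.role} for s in m.species],
            "reactions": [
                {"id": r.id, "stoichiometry": dict(r.stoichiometry),
                 "rate_law": r.rate_law, "params": dict(r.params)}
                for r in m.reactions
            ],
            "params": dict(m.params),
            "bounds": {k: list(v) for k, v in m.bounds.items()},
        }
        m2 = model_from_dict(cfg)
        assert m2.species_ids == m.species_ids
        assert m2.params == m.params
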