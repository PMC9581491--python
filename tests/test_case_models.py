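"""Case-model families: chains, structural triggers, SIR(S) dynamics."""

import numpy as np
import pytest

from effdim.case_models import (
    ChainSpec,
    Compartment,
    SirsVariantSpec,
    TriggerSpec,
    audit_chain,
    audit_sirs,
    audit_upgrades,
    default_sirs_spec,
    integrate_sirs,
    irrigation_chain,
    psacoin_chain,
    run_chain,
    trigger_select,
)
from effdim.effective_dimension import effective_dimensions
from effdim.errors import ChainSpecError
from effdim.estimators import estimate_indices
from effdim.sampling import MarginalSpec, apply_marginals, build_design, split_outputs

U01 = MarginalSpec("uniform", {"low": 0.0, "high": 1.0})


class TestChains:
    def test_undeclared_input_rejected(self):
        with pytest.raises(ChainSpecError, match="undeclared"):
            ChainSpec("bad", {"x1": U01},
                      [Compartment("c", lambda e: e["x2"], ("x2",))])

    def test_unconsumed_input_rejected(self):
        with pytest.raises(ChainSpecError, match="never consumed"):
            ChainSpec("bad", {"x1": U01, "x2": U01},
                      [Compartment("c", lambda e: e["x1"], ("x1",))])

    def test_identity_chain_shares_cv(self):
        chain = ChainSpec("ident", {"x1": U01}, [
            Compartment("c1", lambda e: e["x1"], ("x1",)),
            Compartment("c2", lambda e: e["c1"], ("c1",)),
        ])
        design = apply_marginals(build_design(2 ** 8, 1), chain.marginals)
        out = run_chain(chain, design)
        assert np.array_equal(out["c1"], out["c2"])

    def test_first_compartment_with_one_uncertain_input_is_one_dimensional(self):
        chain = ChainSpec("two-stage", {"x1": U01, "x2": U01}, [
            Compartment("y1", lambda e: 2.0 * e["x1"], ("x1",)),
            Compartment("y2", lambda e: e["y1"] + e["x2"], ("y1", "x2")),
        ])
        design = apply_marginals(build_design(2 ** 11, 2, subset_orders=(2,)), chain.marginals)
        outputs = run_chain(chain, design)
        dims1 = effective_dimensions(estimate_indices(design, outputs=split_outputs(design, outputs["y1"])))
        assert dims1.k_t == 1 and dims1.k_s.value == 1
        # downstream additive stage with equal variances: both inputs influential
        dims2 = effective_dimensions(estimate_indices(design, outputs=split_outputs(design, outputs["y2"])))
        assert dims2.k_t == 2 and dims2.k_s.value == 1

    def test_untransformed_design_rejected(self):
        chain = ChainSpec("ident", {"x1": U01}, [Compartment("c1", lambda e: e["x1"], ("x1",))])
        with pytest.raises(ChainSpecError, match="transformed"):
            run_chain(chain, build_design(16, 1))


class TestTrigger:
    def test_equiprobable_options(self):
        trig = TriggerSpec(("opt1", "opt2"), (0.5, 0.5))
        assert trigger_select(0.49, trig) == 0
        assert trigger_select(0.51, trig) == 1
        assert trigger_select(0.5, trig) == 1  # half-open boundary

    def test_three_weighted_options(self):
        trig = TriggerSpec(("a", "b", "c"), (0.2, 0.3, 0.5))
        assert trigger_select(0.25, trig) == 1
        assert np.array_equal(trigger_select(np.array([0.0, 0.19, 0.2, 0.7]), trig),
                              np.array([0, 0, 1, 2]))

    def test_invalid_specs(self):
        with pytest.raises(ChainSpecError):
            TriggerSpec(("only",), (1.0,))
        with pytest.raises(ChainSpecError):
            TriggerSpec(("a", "b"), (0.6, 0.6))
        trig = TriggerSpec(("a", "b"), (0.5, 0.5))
        with pytest.raises(ValueError):
            trigger_select(1.0, trig)


class TestIrrigation:
    def test_uncertain_trigger_boosts_final_compartment_cv(self):
        """Structural uncertainty in the reference-ET equation propagates a
        larger CV to the withdrawal stage than either fixed equation."""
        cvs = {}
        for mode in ("penman-monteith", "priestley-taylor", "uncertain"):
            table = audit_chain(irrigation_chain(mode), N=2 ** 9, subset_orders=())
            cvs[mode] = table.set_index("compartment").loc["withdrawal", "CV"]
        assert cvs["uncertain"] >= cvs["penman-monteith"]
        assert cvs["uncertain"] >= cvs["priestley-taylor"]

    def test_fixed_modes_drop_the_trigger_input(self):
        assert "trigger" in irrigation_chain("uncertain").inputs
        assert "trigger" not in irrigation_chain("penman-monteith").inputs

    def test_audit_table_shape(self):
        table = audit_chain(irrigation_chain("uncertain"), N=2 ** 7, subset_orders=(2,))
        assert list(table.compartment) == ["et0", "etc", "withdrawal"]
        assert (table.k == 8).all()
        assert table.CV.notna().all()


class TestSirs:
    @pytest.mark.parametrize("variant", ["SIR(S)", "SIR(S-V)", "SIR(S-E)"])
    def test_conservation_and_nonnegativity(self, variant, rng):
        spec = default_sirs_spec(variant, n_times=41)
        for _ in range(5):
            params = {r: m.ppf(rng.random()) for r, m in spec.params.items()}
            traj = integrate_sirs(spec, params)
            assert np.all(traj >= 0.0)
            assert np.max(np.abs(traj.sum(axis=1) - 1.0)) < 1e-6

    def test_zero_transmission_freezes_susceptibles(self):
        spec = default_sirs_spec("SIR(S)", n_times=21)
        params = dict(beta=0.0, gamma=0.1, delta=0.005, eps=0.8, alpha=0.5)
        traj = integrate_sirs(spec, params)
        assert np.allclose(traj[:, 0], traj[0, 0], atol=1e-9)

    def test_subcritical_outbreak_shrinks(self):
        spec = default_sirs_spec("SIR(S)", t_max=60.0, n_times=21)
        params = dict(beta=0.05, gamma=0.2, delta=0.001, eps=0.8, alpha=0.5)
        traj = integrate_sirs(spec, params)
        infected = traj[:, 1] + traj[:, 4]
        assert np.all(np.diff(infected) < 0.0)

    def test_negative_rate_rejected(self):
        spec = default_sirs_spec("SIR(S)")
        with pytest.raises(ValueError, match="non-negative"):
            integrate_sirs(spec, dict(beta=-0.1, gamma=0.1, delta=0.01, eps=0.5, alpha=0.5))

    def test_missing_rate_rejected(self):
        spec = default_sirs_spec("SIR(S)")
        with pytest.raises(ValueError, match="missing"):
            integrate_sirs(spec, dict(beta=0.3))

    def test_bad_initial_state_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SirsVariantSpec("SIR(S)", default_sirs_spec("SIR(S)").params,
                            t_grid=[0.0, 1.0], y0=[0.5, 0.1, 0.0, 0.0, 0.0])


class TestAudits:
    def test_psacoin_audit_emits_one_row_per_stage(self):
        table = audit_upgrades("psacoin", N=2 ** 8, subset_orders=(2,))
        assert list(table.compartment) == ["waste", "buffer", "geosphere", "biosphere"]
        waste = table.iloc[0]
        assert waste.k_t == 1 and waste.k_s == "1"

    def test_sirs_audit_rows_cover_states_and_times(self):
        spec = default_sirs_spec("SIR(S)", n_times=21)
        table = audit_sirs(spec, N=2 ** 4, time_points=(100.0, 200.0), subset_orders=())
        assert set(table.compartment) <= set(spec.state_names)
        assert set(table.time) <= {100.0, 200.0}
        assert len(table) == len(set(zip(table.compartment, table.time)))

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            audit_upgrades("nuclear-winter")
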