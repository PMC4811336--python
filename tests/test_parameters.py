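"""Parameter registry: validation, variants, round-tripping."""

import io

import pytest
import yaml

from striatal_stdp.parameters import (
    ENZYME_RATE_PARAMS,
    ModelVariant,
    ParameterSet,
    apply_variant,
    load_default_parameters,
    load_parameters,
)


class TestLoading:
    def test_defaults_load_and_validate(self, params):
        assert params.n_PKA == 3
        assert params.W_pre_max == 3.0
        assert params.A_AEA == 0.10
        assert params.theta_LTD_start < params.theta_LTD_stop < params.theta_LTP_start

    def test_missing_symbol_is_named(self, params):
        doc = params.to_dict()
        del doc["tau_G"]
        with pytest.raises(ValueError, match="tau_G"):
            ParameterSet(doc)

    def test_unknown_key_rejected(self, params):
        doc = params.to_dict()
        doc["no_such_rate"] = 1.0
        with pytest.raises(ValueError, match="no_such_rate"):
            ParameterSet(doc)

    def test_nonpositive_rate_rejected(self, params):
        with pytest.raises(ValueError, match="tau_G"):
            params.replace(tau_G=-1.0)
        with pytest.raises(ValueError, match="r_MAGL"):
            params.replace(r_MAGL=0.0)  # zero only allowed via variants

    def test_threshold_ordering_enforced(self, params):
        with pytest.raises(ValueError, match="theta"):
            params.replace(theta_LTP_start=params.theta_LTD_start / 2)

    def test_yaml_round_trip_identical(self, params, tmp_path):
        path = tmp_path / "p.yaml"
        params.to_yaml(path)
        again = load_parameters(path)
        assert again == params
        assert again.digest() == params.digest()

    def test_load_from_file_object(self, params):
        buf = io.StringIO(yaml.safe_dump(params.to_dict()))
        assert load_parameters(buf) == params


class TestVariants:
    def test_identity_variant_is_noop(self, params):
        v = ModelVariant(enzyme_scales={"MAGL": 1.0, "DAGK": 1.0})
        assert v.is_identity
        assert apply_variant(params, v) == params

    def test_enzyme_scaling(self, params):
        v = ModelVariant(enzyme_scales={"MAGL": 0.4})
        p = apply_variant(params, v)
        assert p.r_MAGL == pytest.approx(0.4 * params.r_MAGL)
        assert p.r_DAGK == params.r_DAGK

    def test_full_inhibition_pair(self, params):
        v = ModelVariant(enzyme_scales={"MAGL": 0.0, "DAGK": 0.05})
        p = apply_variant(params, v)
        assert p.r_MAGL == 0.0
        assert p.r_DAGK == pytest.approx(0.05 * params.r_DAGK)

    def test_knockouts(self, params):
        p = apply_variant(params, ModelVariant(cb1r_knockout=True))
        assert p.alpha_CB1R == 0.0
        p = apply_variant(params, ModelVariant(nmdar_knockout=True))
        assert p.CaM_T == 0.0

    def test_base_unmodified(self, params):
        before = params.to_dict()
        apply_variant(params, ModelVariant(enzyme_scales={"FAAH": 0.2}))
        assert params.to_dict() == before

    def test_scaling_is_multiplicative_and_knockout_idempotent(self, params):
        a = apply_variant(params, ModelVariant(enzyme_scales={"MAGL": 0.5}))
        ab = apply_variant(a, ModelVariant(enzyme_scales={"MAGL": 0.8}))
        direct = apply_variant(params, ModelVariant(enzyme_scales={"MAGL": 0.4}))
        assert ab.r_MAGL == pytest.approx(direct.r_MAGL)
        ko = ModelVariant(cb1r_knockout=True, nmdar_knockout=True)
        once = apply_variant(params, ko)
        twice = apply_variant(once, ko)
        assert once == twice

    def test_fraction_bounds(self):
        with pytest.raises(ValueError, match="fraction"):
            ModelVariant(enzyme_scales={"MAGL": 1.5})
        with pytest.raises(ValueError, match="unknown enzyme"):
            ModelVariant(enzyme_scales={"PLC": 0.5})

    def test_all_enzyme_names_map_to_parameters(self, params):
        for pname in ENZYME_RATE_PARAMS.values():
            assert pname in params
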