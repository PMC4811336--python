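"""Typed registry of all model parameters.

Every rate constant, conductance, threshold and structural constant of the
model lives here, keyed by the symbol names used throughout the signaling
literature (ASCII transliterations, e.g. ``theta_LTP_start`` for
:math:`\\theta_{LTD}^{start}`).  The default values ship in
``data/default_params.yaml``; that file round-trips losslessly through
:func:`ParameterSet.to_yaml` / :func:`load_default_parameters`.

Pathway knockouts and enzyme inhibition experiments are expressed as a
:class:`ModelVariant` overlay applied with :func:`apply_variant`, which never
mutates the base set.

Units convention: time s, voltage mV, concentration uM, conductance nS,
current pA, capacitance nF (so pA/nF = mV/s).
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import yaml

__all__ = [
    "ParamSpec",
    "ParameterSet",
    "ModelVariant",
    "PARAM_SPECS",
    "ENZYME_RATE_PARAMS",
    "load_default_parameters",
    "load_parameters",
    "apply_variant",
]


@dataclass(frozen=True)
class ParamSpec:
    """Schema entry for a single model parameter."""

    name: str
    default: float
    unit: str
    group: str
    doc: str
    # sign constraint: "pos" (strictly > 0), "nonneg" (>= 0), "free"
    sign: str = "pos"
    integer: bool = False


def _specs() -> list[ParamSpec]:
    P = ParamSpec
    return [
        # --- membrane / channels -------------------------------------------------
        P("C_m", 0.08, "nF", "membrane", "membrane capacitance of the isopotential postsynaptic compartment"),
        P("g_L", 8.0, "nS", "membrane", "leak conductance"),
        P("V_L", -75.0, "mV", "membrane", "leak reversal potential (MSN resting potential)", sign="free"),
        P("g_AMPA", 2.0, "nS", "membrane", "AMPAR maximal conductance"),
        P("g_NMDA", 1.5, "nS", "membrane", "NMDAR maximal conductance"),
        P("g_VSCC", 0.3, "nS", "membrane", "L-type (Cav1.3) voltage-sensitive calcium channel maximal conductance"),
        P("g_TRPV1", 0.4, "nS", "membrane", "TRPV1 maximal conductance"),
        P("E_glu", 0.0, "mV", "membrane", "AMPAR/NMDAR reversal potential", sign="free"),
        P("E_Ca", 120.0, "mV", "membrane", "calcium channel reversal potential", sign="free"),
        P("alpha_AMPA", 1.1, "1/(uM s)", "membrane", "AMPAR two-state binding rate"),
        P("beta_AMPA", 190.0, "1/s", "membrane", "AMPAR two-state unbinding rate"),
        P("alpha_NMDA", 0.2, "1/(uM s)", "membrane", "NMDAR two-state binding rate"),
        P("beta_NMDA", 70.0, "1/s", "membrane", "NMDAR two-state unbinding rate"),
        P("Mg_out", 1.0, "mM", "membrane", "extracellular magnesium (voltage-dependent NMDAR block)"),
        P("Mg_K", 3.57, "mM", "membrane", "magnesium block concentration constant"),
        P("Mg_slope", 0.062, "1/mV", "membrane", "magnesium block voltage slope"),
        P("V_m_half", -25.0, "mV", "membrane", "Cav1.3 activation half voltage", sign="free"),
        P("k_m_VSCC", 6.7, "mV", "membrane", "Cav1.3 activation slope"),
        P("tau_m_VSCC", 0.0005, "s", "membrane", "Cav1.3 activation time constant"),
        P("V_h_half", -13.4, "mV", "membrane", "Cav1.3 inactivation half voltage", sign="free"),
        P("k_h_VSCC", 11.9, "mV", "membrane", "Cav1.3 inactivation slope"),
        P("tau_h_VSCC", 0.0143, "s", "membrane", "Cav1.3 inactivation time constant"),
        P("V_TRPV1_half", 150.0, "mV", "membrane", "TRPV1 open-probability half voltage without agonist", sign="free"),
        P("k_TRPV1", 25.0, "mV", "membrane", "TRPV1 voltage slope"),
        P("dV_TRPV1", 210.0, "mV", "membrane", "leftward shift of TRPV1 half voltage at saturating AEA"),
        P("K_AEA_TRPV1", 1.0, "uM", "membrane", "AEA concentration for half-maximal TRPV1 gating shift"),
        P("xi_NMDA", 18.0, "uM/(pA s)", "membrane", "NMDAR current to calcium-flux conversion"),
        P("xi_VSCC", 0.4, "uM/(pA s)", "membrane", "VSCC current to calcium-flux conversion"),
        P("xi_TRPV1", 4.0, "uM/(pA s)", "membrane", "TRPV1 current to calcium-flux conversion"),
        # --- stimuli -------------------------------------------------------------
        P("G_max", 1500.0, "uM", "stimuli", "peak cleft glutamate per presynaptic spike"),
        P("tau_G", 0.003, "s", "stimuli", "glutamate clearance time constant"),
        P("DC_max", 330.0, "pA", "stimuli", "amplitude of the somatic depolarizing current step"),
        P("DC_dur", 0.030, "s", "stimuli", "duration of the depolarizing current step"),
        P("AP_max", 2400.0, "pA", "stimuli", "amplitude of the spike (bAP) action current"),
        P("delta", 0.003, "s", "stimuli", "delay between step onset and bAP onset"),
        P("tau_bAP", 0.002, "s", "stimuli", "bAP action-current decay time constant"),
        # --- calcium / ER --------------------------------------------------------
        P("B_T", 25.0, "uM", "calcium", "total endogenous fast calcium buffer"),
        P("K_dB", 10.0, "uM", "calcium", "buffer dissociation constant"),
        P("Ca_b", 0.1, "uM", "calcium", "basal cytosolic calcium"),
        P("tau_Cab", 0.02, "s", "calcium", "cytosolic calcium extrusion time constant"),
        P("rho_ER", 0.185, "", "calcium", "ER-to-cytoplasm volume ratio (scales ER depletion)"),
        P("r_C", 179.0, "1/s", "calcium", "maximal IP3R (CICR) release rate"),
        P("r_L", 0.11, "1/s", "calcium", "ER leak rate"),
        P("v_ER", 14.3, "uM/s", "calcium", "maximal SERCA pump rate"),
        P("K_ER", 0.2, "uM", "calcium", "SERCA half-activation calcium"),
        P("d_1", 0.13, "uM", "calcium", "IP3R: IP3 dissociation constant"),
        P("d_2", 1.049, "uM", "calcium", "IP3R: calcium inactivation dissociation constant"),
        P("d_3", 0.9434, "uM", "calcium", "IP3R: IP3 dissociation constant (inactivation coupling)"),
        P("d_5", 0.08234, "uM", "calcium", "IP3R: calcium activation dissociation constant"),
        P("a_2", 0.2, "1/(uM s)", "calcium", "IP3R inactivation gate rate"),
        # --- IP3 production / degradation ---------------------------------------
        P("v_beta", 19.0, "uM/s", "ip3", "maximal mGluR/PLCbeta IP3 (and DAG) production rate"),
        P("K_R", 50.0, "uM", "ip3", "glutamate affinity of the mGluR/PLCbeta cascade"),
        P("n_G", 0.7, "", "ip3", "glutamate cooperativity of PLCbeta activation"),
        P("K_pi", 0.52, "uM", "ip3", "calcium cofactor affinity of PLCbeta"),
        P("n_pi", 4.0, "", "ip3", "calcium cofactor cooperativity of PLCbeta"),
        P("v_delta", 0.0096, "uM/s", "ip3", "maximal PLCdelta production rate"),
        P("kappa_delta", 1.5, "uM", "ip3", "IP3 inhibition constant of PLCdelta"),
        P("K_PLCdelta", 0.1, "uM", "ip3", "calcium affinity of PLCdelta"),
        P("r_5P", 0.104, "1/s", "ip3", "IP3 degradation rate by IP-5P"),
        P("v_3K", 1.0, "uM/s", "ip3", "maximal IP3K degradation rate (CaMKII dependent)"),
        P("K_3", 1.0, "uM", "ip3", "IP3 affinity of IP3K"),
        # --- endocannabinoids ----------------------------------------------------
        P("r_DGL", 93.4, "1/s", "ecb", "DAGLalpha maximal turnover rate"),
        P("DAGL_T", 1.0, "uM", "ecb", "total DAGLalpha concentration"),
        P("K_DAGL", 8.8, "uM", "ecb", "DAGLalpha Michaelis constant for DAG"),
        P("r_DAGK", 2.0, "1/s", "ecb", "DAG consumption rate by DAG kinase"),
        P("r_MAGL", 0.286, "1/s", "ecb", "2-AG degradation rate (MAG-lipase + spillover)"),
        P("r_k", 91.0, "1/(uM^n_c s)", "ecb", "DAGLalpha calcium-activation on-rate"),
        P("r_p", 2.63, "1/s", "ecb", "DAGLalpha deactivation rate"),
        P("n_c", 4.0, "", "ecb", "calcium cooperativity of DAGLalpha activation"),
        P("nu_AT", 0.2, "1/s", "ecb", "lumped NAPE-pathway AEA synthesis rate per unit calcium"),
        P("r_FAAH", 1.0, "uM/s", "ecb", "maximal AEA degradation rate by FAAH"),
        P("K_FAAH", 1.0, "uM", "ecb", "AEA Michaelis constant of FAAH"),
        # --- CB1R ----------------------------------------------------------------
        P("alpha_CB1R", 4.39, "1/(uM s)", "cb1r", "CB1R opening rate per unit eCB", sign="nonneg"),
        P("beta_CB1R", 0.631, "1/s", "cb1r", "CB1R closing rate"),
        P("gamma_CB1R", 0.159, "1/s", "cb1r", "CB1R desensitization rate"),
        P("epsilon_CB1R", 0.0043, "1/s", "cb1r", "CB1R recovery rate from desensitization"),
        P("A_AEA", 0.10, "", "cb1r", "partial-agonism factor of AEA at CB1R"),
        # --- presynaptic plasticity rule ----------------------------------------
        P("k_CB1R", 1.0, "", "plasticity", "gain from open-CB1R fraction to plasticity drive y_CB1R"),
        P("D_1", 0.01, "", "plasticity", "tonic offset of y_CB1R (e.g. tonic dopamine)", sign="nonneg"),
        P("D_2", 0.01, "", "plasticity", "tonic offset of the tau_Wpre drive", sign="nonneg"),
        P("theta_LTD_start", 0.06, "", "plasticity", "lower edge of the LTD band of y_CB1R"),
        P("theta_LTD_stop", 0.13, "", "plasticity", "upper edge of the LTD band of y_CB1R"),
        P("theta_LTP_start", 0.16, "", "plasticity", "LTP threshold of y_CB1R"),
        P("A_LTD", 0.6, "", "plasticity", "LTD depth (W_pre target 1 - A_LTD)"),
        P("A_LTP", 1.5, "", "plasticity", "LTP drive (W_pre target 1 + A_LTP, clipped)"),
        P("P_1", 0.00022, "s", "plasticity", "tau_Wpre numerator constant"),
        P("P_2", 0.02, "", "plasticity", "tau_Wpre half-drive constant"),
        P("P_3", 4.0, "", "plasticity", "tau_Wpre drive exponent"),
        P("P_4", 3.0, "s", "plasticity", "tau_Wpre floor (fast limit)"),
        P("W_pre_max", 3.0, "", "plasticity", "hard ceiling of the presynaptic weight"),
        P("w_post_gain", 3.5, "", "plasticity", "gain of W_post on the phosphorylated CaMKII fraction"),
        P("use_smooth_omega", 0.0, "bool", "plasticity", "0: sharp threshold rule, 1: smooth sigmoidal rule", sign="nonneg"),
        P("k_S", 2.0, "", "plasticity", "steepness of the smooth threshold rule"),
        # --- CaMKII subsystem ----------------------------------------------------
        P("CaM_T", 10.0, "uM", "camkii", "total calmodulin", sign="nonneg"),
        P("K_CaM1", 2.4, "uM", "camkii", "calmodulin site-1 calcium dissociation constant"),
        P("K_CaM2", 2.4, "uM", "camkii", "calmodulin site-2 calcium dissociation constant"),
        P("K_CaM3", 0.22, "uM", "camkii", "calmodulin site-3 calcium dissociation constant"),
        P("K_CaM4", 0.22, "uM", "camkii", "calmodulin site-4 calcium dissociation constant"),
        P("K_5", 25.0, "uM", "camkii", "(Ca)4CaM affinity of a CaMKII subunit"),
        P("CaMKII_T", 5.55, "uM", "camkii", "total CaMKII holoenzyme (6-subunit rings)"),
        P("k_6", 0.55, "1/s", "camkii", "initiation autophosphorylation rate (two bound CaM)"),
        P("k_7", 14.0, "1/s", "camkii", "propagation autophosphorylation rate (one bound CaM)"),
        P("k_12", 6.0, "1/s", "camkii", "PP1 catalytic dephosphorylation rate constant"),
        P("K_M", 0.4, "uM", "camkii", "PP1 Michaelis constant for phosphorylated subunits"),
        P("PP1_T", 0.2, "uM", "camkii", "total protein phosphatase 1"),
        P("I1_T", 2.0, "uM", "camkii", "total inhibitor-1 (DARPP-32 analog)"),
        P("k_11", 500.0, "1/(uM s)", "camkii", "PP1 inhibition rate by phosphorylated I1"),
        P("km_11", 0.3, "1/s", "camkii", "PP1:I1p complex dissociation rate"),
        P("k_PKA0", 0.002, "1/s", "camkii", "basal PKA activity on I1"),
        P("k_PKA", 0.005, "1/s", "camkii", "calcium-stimulated PKA activity on I1"),
        P("K_PKA", 2.0, "uM", "camkii", "calcium half-activation of PKA (via B72-PP2A/DARPP-32)"),
        P("n_PKA", 3.0, "", "camkii", "Hill exponent of PKA activation by calcium", integer=True),
        P("k_CaN0", 0.005, "1/s", "camkii", "basal calcineurin activity on I1p"),
        P("k_CaN", 0.005, "1/s", "camkii", "calcium-stimulated calcineurin activity on I1p"),
        P("K_CaN", 0.45, "uM", "camkii", "calcium half-activation of calcineurin"),
        P("n_CaN", 3.0, "", "camkii", "Hill exponent of calcineurin activation", integer=True),
        # --- numerics ------------------------------------------------------------
        P("rtol", 1e-7, "", "numerics", "relative integration tolerance"),
        P("atol", 1e-7, "", "numerics", "absolute integration tolerance"),
        P("blur_sd_ms", 3.0, "ms", "numerics", "s.d. of the Gaussian spike-timing blur"),
        P("settle_time", 300.0, "s", "numerics", "post-protocol settling horizon before weights are read"),
        P("record_dt", 0.001, "s", "numerics", "trajectory sampling step during the protocol"),
        P("settle_record_dt", 0.5, "s", "numerics", "trajectory sampling step during settling"),
    ]


PARAM_SPECS: dict[str, ParamSpec] = {s.name: s for s in _specs()}

#: enzyme names accepted by ModelVariant.enzyme_scales -> scaled parameter
ENZYME_RATE_PARAMS: dict[str, str] = {
    "MAGL": "r_MAGL",
    "DAGK": "r_DAGK",
    "DAGL": "r_DGL",
    "FAAH": "r_FAAH",
}


class ParameterSet(Mapping[str, float]):
    """Immutable, validated mapping of parameter name to value.

    Supports attribute access (``params.tau_G``) and the full Mapping
    protocol.  ``allow_zero`` relaxes the strict-positivity check for the
    parameters that knockout/inhibition variants may drive to zero.
    """

    _ZEROABLE = frozenset(
        list(ENZYME_RATE_PARAMS.values())
        + ["alpha_CB1R", "CaM_T", "g_AMPA", "g_NMDA", "g_VSCC", "g_TRPV1"]
    )

    def __init__(self, values: Mapping[str, float], allow_zero: bool = False):
        unknown = sorted(set(values) - set(PARAM_SPECS))
        if unknown:
            raise ValueError(f"unknown parameter(s): {', '.join(unknown)}")
        missing = sorted(set(PARAM_SPECS) - set(values))
        if missing:
            raise ValueError(f"missing parameter(s): {', '.join(missing)}")
        vals = {k: float(values[k]) for k in PARAM_SPECS}
        self._values = vals
        self._validate(allow_zero)

    # -- validation ----------------------------------------------------------
    def _validate(self, allow_zero: bool) -> None:
        for name, spec in PARAM_SPECS.items():
            v = self._values[name]
            if v != v or v in (float("inf"), float("-inf")):
                raise ValueError(f"parameter {name} is not finite: {v!r}")
            if spec.sign == "pos":
                ok_zero = allow_zero and name in self._ZEROABLE
                if v < 0 or (v == 0 and not ok_zero):
                    raise ValueError(f"parameter {name} must be strictly positive, got {v}")
            elif spec.sign == "nonneg" and v < 0:
                raise ValueError(f"parameter {name} must be non-negative, got {v}")
            if spec.integer and abs(v - round(v)) > 1e-12:
                raise ValueError(f"parameter {name} must be an integer, got {v}")
        t1, t2, t3 = (self._values[k] for k in ("theta_LTD_start", "theta_LTD_stop", "theta_LTP_start"))
        if not (t1 < t2 < t3):
            raise ValueError(
                f"plasticity thresholds must satisfy theta_LTD_start < theta_LTD_stop "
                f"< theta_LTP_start, got {t1}, {t2}, {t3}"
            )
        if not (0 < self._values["A_LTD"] <= 1):
            raise ValueError(f"A_LTD must lie in (0, 1], got {self._values['A_LTD']}")
        if self._values["use_smooth_omega"] not in (0.0, 1.0):
            raise ValueError("use_smooth_omega must be 0 or 1")

    # -- Mapping protocol ------------------------------------------------------
    def __getitem__(self, key: str) -> float:
        return self._values[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def __getattr__(self, name: str) -> float:
        try:
            return self.__dict__["_values"][name]
        except KeyError:
            raise AttributeError(name) from None

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ParameterSet) and self._values == other._values

    def __repr__(self) -> str:
        return f"ParameterSet({len(self._values)} parameters)"

    # -- derived quantities ----------------------------------------------------
    @property
    def CaMKII_act_max(self) -> float:
        """Total phosphorylatable CaMKII subunit concentration (uM)."""
        return 6.0 * self._values["CaMKII_T"]

    # -- construction / serialization ------------------------------------------
    def replace(self, allow_zero: bool = False, **changes: float) -> "ParameterSet":
        vals = dict(self._values)
        vals.update(changes)
        return ParameterSet(vals, allow_zero=allow_zero)

    def to_dict(self) -> dict[str, float]:
        return dict(self._values)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self._values, fh, sort_keys=True)

    def to_json(self) -> str:
        """JSON export used for provenance in result files."""
        return json.dumps(self._values, sort_keys=True)

    def digest(self) -> str:
        import hashlib

        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass(frozen=True)
class ModelVariant:
    """Pathway knockouts and enzyme inhibition overlays.

    ``enzyme_scales`` maps an enzyme name (MAGL, DAGK, DAGL, FAAH) to the
    fraction of its default maximal rate that remains, e.g. ``{"MAGL": 0.4}``
    emulates non-competitive MAGL inhibition at 40% residual activity.
    """

    nmdar_knockout: bool = False
    cb1r_knockout: bool = False
    enzyme_scales: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, frac in self.enzyme_scales.items():
            if name not in ENZYME_RATE_PARAMS:
                raise ValueError(
                    f"unknown enzyme {name!r}; expected one of {sorted(ENZYME_RATE_PARAMS)}"
                )
            if not (0.0 <= float(frac) <= 1.0):
                raise ValueError(f"enzyme fraction for {name} must lie in [0, 1], got {frac}")

    @property
    def is_identity(self) -> bool:
        return (
            not self.nmdar_knockout
            and not self.cb1r_knockout
            and all(float(f) == 1.0 for f in self.enzyme_scales.values())
        )

    def label(self) -> str:
        parts = []
        if self.nmdar_knockout:
            parts.append("nmdar-ko")
        if self.cb1r_knockout:
            parts.append("cb1r-ko")
        parts += [f"{k.lower()}={float(v):g}" for k, v in sorted(self.enzyme_scales.items())]
        return "+".join(parts) if parts else "control"


def load_parameters(source) -> ParameterSet:
    """Load and validate a parameter set from a YAML document.

    ``source`` may be a path or an open file object.  The document must be a
    flat mapping supplying a value for every required symbol; unknown keys
    are rejected.
    """
    if hasattr(source, "read"):
        doc = yaml.safe_load(source.read())
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError("parameter document must be a flat key: value mapping")
    return ParameterSet(doc)


def load_default_parameters() -> ParameterSet:
    """Load the shipped default parameter file."""
    ref = importlib.resources.files("striatal_stdp").joinpath("data/default_params.yaml")
    with ref.open() as fh:
        return load_parameters(fh)


def apply_variant(base: ParameterSet, variant: ModelVariant) -> ParameterSet:
    """Return a new ParameterSet with the variant overlay applied.

    Enzyme maximal rates are multiplied by the given fractions.  A CB1R
    knockout pins receptor activation to zero (``alpha_CB1R = 0`` with the
    receptor initialized closed), so CB1R activation stays null whatever the
    eCB levels.  An NMDAR-signaling knockout removes the pathway downstream
    of NMDAR (calmodulin, hence CaMKII), so ``W_post`` stays 1; calcium
    influx itself is untouched.
    """
    changes: dict[str, float] = {}
    for enzyme, frac in variant.enzyme_scales.items():
        pname = ENZYME_RATE_PARAMS[enzyme]
        changes[pname] = base[pname] * float(frac)
    if variant.cb1r_knockout:
        changes["alpha_CB1R"] = 0.0
    if variant.nmdar_knockout:
        changes["CaM_T"] = 0.0
    return base.replace(allow_zero=True, **changes)


def write_default_yaml(path) -> None:
    """Write the schema defaults as an annotated YAML file (units in comments)."""
    groups: dict[str, list[ParamSpec]] = {}
    for spec in PARAM_SPECS.values():
        groups.setdefault(spec.group, []).append(spec)
    with open(path, "w") as fh:
        fh.write("# Default model parameters. Flat mapping: symbol -> value.\n")
        fh.write("# Units and meaning are given in trailing comments.\n")
        for group, specs in groups.items():
            fh.write(f"\n# --- {group} ---\n")
            for s in specs:
                unit = f" [{s.unit}]" if s.unit else ""
                fh.write(f"{s.name}: {s.default!r}  #{unit} {s.doc}\n")
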