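"""Built-in node models.

Four node kinds are shipped:

``elowitz``
    Minimal transcription-factor node (mRNA + protein) with Hill-type
    repression/activation of transcription.  The classic three-node cyclic
    repression circuit built from these nodes is the repressilator.
``tomazou``
    Refined transcription-factor node: translation first yields an unfolded
    protein that matures into the active folded form; all species are diluted
    by growth, and folded protein can additionally be degraded by shared
    proteases with Michaelis-Menten queueing.
``crispri`` / ``crispri_nonosc``
    CRISPR-interference node: a composite transcript is cleaved (Csy4) into an
    sgRNA and a reporter mRNA; the sgRNA loads onto dCas9 and the complex
    occludes the *target* node's promoter DNA by explicit binding reactions,
    so repressors compete for free promoter states rather than entering a
    Hill factor.  The ``crispri_nonosc`` preset differs only in the bound-DNA
    dissociation rate (kr_dsd = 0.7762 min^-1) and a slower dilution rate
    (k_d = 0.005 min^-1), the regime of cells growing on a solid surface,
    where the three-node ring settles to a fixed point instead of cycling.
``hill_protein``
    Protein-only node (instant mRNA limit); used by the spatial
    activator-inhibitor example where a two-variable system is wanted.

Rate-name convention: ``kf_*`` are association and ``kr_*`` dissociation rate
constants (so ``kr_dsd`` is the dissociation of the dCas:sgRNA complex from
DNA).  Units are nM and minutes throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

import numpy as np

from .circuit import (
    Circuit,
    InputChannel,
    NodeModelSpec,
    ReactionTemplate,
    register_model,
)

__all__ = [
    "ElowitzParams",
    "TomazouParams",
    "CrisprParams",
    "TwoInputHillParams",
    "hill_repression",
    "hill_activation",
    "two_input_hill",
    "elowitz_rhs",
    "tomazou_rhs",
    "crispri_reactions",
]


def _positive(obj) -> None:
    for f in fields(obj):
        v = getattr(obj, f.name)
        if not v > 0:
            raise ValueError(f"{type(obj).__name__}.{f.name} must be positive, got {v}")


# ---------------------------------------------------------------------------
# parameter sets (defaults are this package's canonical choices; see docs)


@dataclass(frozen=True)
class ElowitzParams:
    """Transcription-factor node parameters.

    Defaults put the node in a tightly cooperative, moderately driven
    oscillatory regime: Hill exponent 4, leak 1e-3 of the maximal rate,
    mRNA half-life ~6 min, protein half-life ~20 min, and a promoter
    strength ~7x the Hopf threshold of the three-node ring.  This single
    parameter set (i) gives the three-node ring a period of a few hours,
    (ii) keeps the odd/even oscillation parity of every ring family intact
    under 2-fold perturbation of any rate, and (iii) reproduces the
    approach of the midpoint-rule duty cycle towards ~50% in large rings.
    """

    a1: float = 0.5        # max transcription rate, nM/min
    a0: float = 5.0e-4     # leaky transcription, nM/min
    n: float = 4.0         # Hill exponent
    K: float = 40.0        # repression half-saturation, nM
    d_m: float = 0.1155    # mRNA decay, 1/min  (t1/2 ~ 6 min)
    k_P: float = 2.31      # translation, 1/min per mRNA
    d_P: float = 0.03466   # protein decay, 1/min (t1/2 = 20 min)

    def __post_init__(self):
        _positive(self)
        if self.n < 1:
            raise ValueError("Hill exponent n must be >= 1")


@dataclass(frozen=True)
class TomazouParams:
    """Refined transcription-factor node with folding and dilution."""

    a1: float = 5.0
    a0: float = 5.0e-3
    n: float = 2.0
    K: float = 40.0
    d_m: float = 0.3466    # mRNA decay + dilution, 1/min
    k_P: float = 6.93      # translation -> unfolded protein, 1/min
    k_fold: float = 0.5    # maturation (folding), 1/min
    k_d: float = 0.02      # dilution by growth, 1/min

    def __post_init__(self):
        _positive(self)
        if self.n < 1:
            raise ValueError("Hill exponent n must be >= 1")


@dataclass(frozen=True)
class CrisprParams:
    """CRISPRi node parameters (oscillatory preset).

    The dilution rate is the calibrated value that puts the three-node ring's
    limit-cycle period in the experimentally observed 10-11 h window; the
    non-oscillatory preset replaces ``kr_dsd`` by 0.7762 min^-1 and ``k_d``
    by 0.005 min^-1 (slow growth on solid medium).
    """

    a1: float = 2.0        # transcription per free promoter, 1/min
    k_csy: float = 0.3     # Csy4 cleavage of the composite transcript, 1/min
    k_P: float = 2.0       # reporter translation, 1/min
    d_P: float = 0.02      # reporter decay + dilution, 1/min
    c_cas: float = 10.0    # total dCas9 pool, nM (limiting: titration relay)
    kf_ds: float = 0.1     # dCas + sgRNA association, 1/(nM min)
    kr_ds: float = 0.01    # dCas:sgRNA dissociation, 1/min
    kf_dsd: float = 3.0    # dCas:sgRNA + DNA association, 1/(nM min)
    kr_dsd: float = 1.0e-3  # bound-DNA dissociation, 1/min
    k_d: float = 0.008     # dilution, 1/min (calibrated: ring period ~10.8 h)
    d_R: float = 0.1386    # RNA degradation beyond dilution, 1/min (t1/2 ~ 5 min)
    DNA_tot: float = 1.0   # promoter copies per node, nM

    def __post_init__(self):
        _positive(self)


@dataclass(frozen=True)
class TwoInputHillParams:
    """Two-input competitive Hill response (chemical inducer x light).

    ``k_light`` < 1 encodes a light arm weaker than the chemical arm, the
    regime in which adding light *lowers* expression at saturating inducer
    (promoter competition).  ``F_0``/``F_max`` scale model activity to
    instrument fluorescence units.
    """

    K_ara: float = 1.0e-3   # % w/v arabinose at half-saturation
    n_ara: float = 1.0
    K_light: float = 30.0   # % of device max intensity at half-saturation
    n_light: float = 2.0
    k_light: float = 0.125  # relative strength of the light arm
    F_max: float = 4.0e4    # fluorescence scale, au
    F_0: float = 1.0e3      # basal offset, au

    def __post_init__(self):
        for name in ("K_ara", "n_ara", "K_light", "n_light", "k_light", "F_max"):
            if not getattr(self, name) > 0:
                raise ValueError(f"TwoInputHillParams.{name} must be positive")
        if self.F_0 < 0:
            raise ValueError("TwoInputHillParams.F_0 must be >= 0")


# ---------------------------------------------------------------------------
# elementary response functions


def hill_repression(R, K, n):
    """1/(1+(R/K)^n), in [0, 1]."""
    return 1.0 / (1.0 + (np.asarray(R, float) / K) ** n)


def hill_activation(R, K, n):
    """(R/K)^n/(1+(R/K)^n), in [0, 1)."""
    x = (np.asarray(R, float) / K) ** n
    return x / (1.0 + x)


def two_input_hill(ara, I, params: TwoInputHillParams):
    """Competitive two-input activity in [0, max(1, k_light)].

    activity = (x + k_light*y) / ((1+x)(1+y)) with x, y the Hill terms of the
    chemical and light arms.  Saturating chemical alone gives 1; saturating
    light alone gives k_light; with both present the weaker arm dilutes the
    stronger one's occupancy (competition for the same promoter).
    """
    ara = np.asarray(ara, dtype=float)
    I = np.asarray(I, dtype=float)
    if np.any(ara < 0) or np.any(I < 0):
        raise ValueError("inputs must be non-negative")
    x = (ara / params.K_ara) ** params.n_ara
    y = (I / params.K_light) ** params.n_light
    out = (x + params.k_light * y) / ((1.0 + x) * (1.0 + y))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# reference right-hand sides (single node; used as oracles and for clarity)


def elowitz_rhs(state, params: ElowitzParams, regulation_factors=()) -> np.ndarray:
    """d/dt of (m, P) for one transcription-factor node.

    ``regulation_factors`` are the already-evaluated multiplicative Hill
    factors of the node's inputs (empty for a constitutive node).
    """
    m, P = state
    if m < 0 or P < 0:
        raise ValueError("negative state")
    reg = float(np.prod(regulation_factors)) if len(regulation_factors) else 1.0
    dm = params.a0 + params.a1 * reg - params.d_m * m
    dP = params.k_P * m - params.d_P * P
    return np.array([dm, dP])


def tomazou_rhs(
    state, params: TomazouParams, regulation_factors=(), protease_pool=None
) -> np.ndarray:
    """d/dt of (m, uP, P) for one refined node.

    ``protease_pool`` is ``None`` or ``(kcat, Km, E, total_substrate)`` where
    ``total_substrate`` is the summed folded protein over every node sharing
    the protease — the shared-queue Michaelis-Menten law
    ``kcat*E*P/(Km + total)`` couples degradation across targets.
    """
    m, uP, P = state
    reg = float(np.prod(regulation_factors)) if len(regulation_factors) else 1.0
    dm = params.a0 + params.a1 * reg - params.d_m * m
    duP = params.k_P * m - params.k_fold * uP - params.k_d * uP
    dP = params.k_fold * uP - params.k_d * P
    if protease_pool is not None:
        kcat, Km, E, total = protease_pool
        if Km <= 0:
            raise ValueError("protease Km must be positive")
        dP -= kcat * E * P / (Km + total)
    return np.array([dm, duP, dP])


# ---------------------------------------------------------------------------
# node-model templates


def _factor_channels():
    return {
        "HILL": InputChannel(kind="factor"),
        "TWOINPUT": InputChannel(kind="factor"),
    }


def _elowitz_spec() -> NodeModelSpec:
    p = ElowitzParams()
    return NodeModelSpec(
        model_id="elowitz",
        species_roles=["m", "P"],
        initial={"m": 0.0, "P": 0.0},
        reactions=[
            ReactionTemplate("transcription", {"m": +1}, "a0+a1*REG", ("HILL", "TWOINPUT")),
            ReactionTemplate("translation", {"P": +1}, "k_P*m"),
            ReactionTemplate("mrna_decay", {"m": -1}, "d_m*m"),
            ReactionTemplate("protein_decay", {"P": -1}, "d_P*P"),
        ],
        input_channels=_factor_channels(),
        parameter_defaults=asdict(p),
        output_role="P",
        protease_substrate_role="P",
    )


def _tomazou_spec() -> NodeModelSpec:
    p = TomazouParams()
    return NodeModelSpec(
        model_id="tomazou",
        species_roles=["m", "uP", "P"],
        initial={"m": 0.0, "uP": 0.0, "P": 0.0},
        reactions=[
            ReactionTemplate("transcription", {"m": +1}, "a0+a1*REG", ("HILL", "TWOINPUT")),
            ReactionTemplate("translation", {"uP": +1}, "k_P*m"),
            ReactionTemplate("maturation", {"uP": -1, "P": +1}, "k_fold*uP"),
            ReactionTemplate("mrna_decay", {"m": -1}, "d_m*m"),
            ReactionTemplate("uP_dilution", {"uP": -1}, "k_d*uP"),
            ReactionTemplate("P_dilution", {"P": -1}, "k_d*P"),
        ],
        input_channels=_factor_channels(),
        parameter_defaults=asdict(p),
        output_role="P",
        protease_substrate_role="P",
    )


def _crispri_inject(compiler, node: str, edges) -> None:
    """Wire CRISPRi repression: dCas pool, sgRNA loading, promoter occlusion.

    Adds (once) the shared free-dCas species with constitutive production
    k_d*c_cas and dilution k_d, so the total pool relaxes to c_cas; per
    regulator a dCas:sgRNA complex with loading/unloading/dilution; and per
    edge the reversible occlusion of the target's free promoter DNA.  Free +
    bound promoter DNA is conserved exactly and recorded as an invariant.
    """
    kd = "k_d"
    compiler.add_param(kd, CrisprParams().k_d)
    compiler.add_param("c_cas", CrisprParams().c_cas)
    if "dCas" not in compiler.species:
        compiler.add_species("dCas", compiler.params["c_cas"])
        compiler.add_reaction("dcas_production", {"dCas": +1}, "k_d*c_cas")
        compiler.add_reaction("dcas_dilution", {"dCas": -1}, "k_d*dCas")
    dna_free = compiler.species_name(node, "DNA_free")
    bound_names = []
    for e in edges:
        reg = e.regulator
        sg = compiler.species_name(reg, "sgRNA")
        if sg not in compiler.species:
            raise ValueError(
                f"CRISPRI edge onto {node!r}: regulator {reg!r} produces no sgRNA"
            )
        cx = f"dCas_sgRNA_{reg}"
        if cx not in compiler.species:
            compiler.add_species(cx, 0.0)
            compiler.add_reaction(
                f"complex_formation_{reg}",
                {"dCas": -1, sg: -1, cx: +1},
                f"kf_ds*dCas*{sg}",
            )
            compiler.add_reaction(
                f"complex_dissociation_{reg}", {"dCas": +1, sg: +1, cx: -1}, f"kr_ds*{cx}"
            )
            compiler.add_reaction(f"complex_dilution_{reg}", {cx: -1}, f"k_d*{cx}")
        dnab = f"DNA_bound_{node}_{reg}"
        compiler.add_species(dnab, 0.0)
        bound_names.append(dnab)
        compiler.add_reaction(
            f"dna_binding_{node}_{reg}",
            {cx: -1, dna_free: -1, dnab: +1},
            f"kf_dsd*{cx}*{dna_free}",
        )
        compiler.add_reaction(
            f"dna_release_{node}_{reg}",
            {cx: +1, dna_free: +1, dnab: -1},
            f"kr_dsd*{dnab}",
        )
        # replication turnover: newly replicated promoter copies are born
        # unbound while the occluded copy dilutes with the old cell material
        # (the bound complex is lost); keeps DNA_free + DNA_bound constant
        compiler.add_reaction(
            f"dna_replication_{node}_{reg}", {dna_free: +1, dnab: -1}, f"k_d*{dnab}"
        )
    compiler.add_conserved(
        f"DNA_total_{node}", {dna_free: 1.0, **{b: 1.0 for b in bound_names}}
    )


def _crispri_spec(model_id: str, p: CrisprParams) -> NodeModelSpec:
    defaults = {k: v for k, v in asdict(p).items() if k != "DNA_tot"}
    channels = _factor_channels()
    channels["CRISPRI"] = InputChannel(kind="reactions")
    return NodeModelSpec(
        model_id=model_id,
        species_roles=["mRNA", "sgRNA", "mRNA_r", "P", "DNA_free"],
        initial={"mRNA": 0.0, "sgRNA": 0.0, "mRNA_r": 0.0, "P": 0.0, "DNA_free": p.DNA_tot},
        reactions=[
            ReactionTemplate(
                "transcription", {"mRNA": +1}, "a1*DNA_free*REG", ("HILL", "TWOINPUT")
            ),
            ReactionTemplate(
                "csy4_cleavage", {"mRNA": -1, "sgRNA": +1, "mRNA_r": +1}, "k_csy*mRNA"
            ),
            ReactionTemplate("translation", {"P": +1}, "k_P*mRNA_r"),
            ReactionTemplate("mrna_decay", {"mRNA": -1}, "(k_d+d_R)*mRNA"),
            ReactionTemplate("sgrna_decay", {"sgRNA": -1}, "(k_d+d_R)*sgRNA"),
            ReactionTemplate("mrna_r_decay", {"mRNA_r": -1}, "(k_d+d_R)*mRNA_r"),
            ReactionTemplate("reporter_decay", {"P": -1}, "d_P*P"),
        ],
        input_channels=channels,
        parameter_defaults=defaults,
        output_role="P",
        injector=_crispri_inject,
        regulator_role="sgRNA",
    )


def _hill_protein_spec() -> NodeModelSpec:
    """Protein-only node: transcription+translation collapsed to one step."""
    return NodeModelSpec(
        model_id="hill_protein",
        species_roles=["P"],
        initial={"P": 0.0},
        reactions=[
            ReactionTemplate("production", {"P": +1}, "a0+a1*REG", ("HILL", "TWOINPUT")),
            ReactionTemplate("decay", {"P": -1}, "d_P*P"),
        ],
        input_channels=_factor_channels(),
        parameter_defaults={
            "a1": 10.0,
            "a0": 1.0e-2,
            "n": 2.0,
            "K": 40.0,
            "d_P": 0.05,
        },
        output_role="P",
        protease_substrate_role="P",
    )


register_model(_elowitz_spec())
register_model(_tomazou_spec())
register_model(_crispri_spec("crispri", CrisprParams()))
register_model(
    _crispri_spec(
        "crispri_nonosc", CrisprParams(kr_dsd=0.7762, k_d=0.005)
    )
)
register_model(_hill_protein_spec())


def crispri_reactions(node: str, incoming_regulators, params: CrisprParams | None = None):
    """Compiled reaction list for one CRISPRi node with the given repressors.

    Builds a throwaway circuit containing ``node`` plus its regulator nodes
    and returns the flattened reactions; useful for inspecting exactly which
    binding/occlusion reactions a CRISPRI edge injects.
    """
    params = params or CrisprParams()
    c = Circuit(default_model="crispri")
    c.add_node(node)
    for reg in incoming_regulators:
        if reg not in c.nodes:
            c.add_node(reg)
        c.add_regulation(f"{node}:CRISPRI |- {reg}")
    for k, v in asdict(params).items():
        if k != "DNA_tot":
            c.set_param(k, v)
    return c.compile().reactions
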