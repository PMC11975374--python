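"""Scenario construction: genotype / infection / tracer conditions.

A :class:`PathwayScenario` fully resolves the hemocyte pathway model for one
experimental condition: which enzyme capacities are scaled by infection,
which are knocked down by RNAi, which tracer the ex vivo medium carries, and
for how long the cells incubate.  Defaults ship as a versioned calibration
fixture (``samtrace/data/default_capacities.yaml``).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .network import PathwayNetwork, Pool, ProductRule, Reaction

GENOTYPES = ("control", "Ahcy-RNAi", "Adk3-RNAi", "Ak1-RNAi")
TRACERS = ("none", "Met-13C5", "Ado-13C5")

#: media tracer concentrations used in the ex vivo incubations (uM)
DEFAULT_TRACER_UM = {"none": 0.0, "Met-13C5": 0.33, "Ado-13C5": 10.0}


def default_parameters() -> dict:
    """Load the shipped calibration fixture (deep copy; safe to mutate)."""
    text = resources.files("samtrace.data").joinpath(
        "default_capacities.yaml").read_text()
    return yaml.safe_load(text)


@dataclass
class PathwayScenario:
    """A resolved simulation condition.

    ``capacities`` are the final per-reaction rate constants after applying
    infection scaling, RNAi knockdown and the nutrient-supply factor; they
    are what :func:`build_network` consumes.
    """

    genotype: str = "control"
    infected: bool = False
    tracer: str = "none"
    tracer_concentration: float | None = None  # uM; None -> tracer default
    tracer_impurity: float = 0.03
    nutrient_supply: float = 1.0
    knockdown_factor: float = 0.1
    duration_min: float = 20.0
    preequilibrate_min: float = 1200.0
    dt_min: float = 0.01
    preeq_dt_min: float = 0.5
    ehna_split: float = 0.5
    sah_inhibition_ki: float = 2.0
    sam_feedback_ki: float = 1.5
    capacities: dict = field(default_factory=dict)
    pool_amounts: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.tracer_concentration is None:
            self.tracer_concentration = DEFAULT_TRACER_UM.get(self.tracer, 0.0)


def build_scenario(config: dict | None = None, **kwargs) -> PathwayScenario:
    """Resolve a structured scenario description into a PathwayScenario.

    Parameters may come from a config mapping, keyword overrides, or both
    (keywords win).  Unknown genotype or tracer names are rejected by name.
    Calibrated default capacities are applied, then condition scaling:

    * infection scales methyltransferase, SAM synthetase, methionine uptake,
      de novo purine synthesis and the inducible (Adk3-like / Ak1-like)
      shares of the kinase capacities upward;
    * RNAi multiplies exactly the targeted enzyme's capacity by
      ``knockdown_factor`` (for Adk3/Ak1 only the inducible share, since the
      constitutive isoforms are untouched by the knockdown);
    * ``nutrient_supply`` scales the ADP -> ATP regeneration capacity.

    Remethylation and the Ahcy-independent Met -> CTH bypass default to zero
    capacity.
    """
    cfg = dict(config or {})
    cfg.update(kwargs)
    params = default_parameters()
    cap_overrides = cfg.pop("capacities", {})
    pool_overrides = cfg.pop("pool_amounts", {})
    scales = params["infection_scales"]

    scen = PathwayScenario(
        **{k: v for k, v in cfg.items() if k in PathwayScenario.__dataclass_fields__}
    )
    unknown = set(cfg) - set(PathwayScenario.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    if scen.genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype: {scen.genotype!r}")
    if scen.tracer not in TRACERS:
        raise ValueError(f"unknown tracer: {scen.tracer!r}")
    if not (0.0 < scen.knockdown_factor < 1.0):
        raise ValueError("knockdown_factor must lie in (0, 1)")
    if not (0.0 < scen.nutrient_supply <= 1.0):
        raise ValueError("nutrient_supply must lie in (0, 1]")
    if not (0.0 <= scen.tracer_impurity < 1.0):
        raise ValueError("tracer_impurity must lie in [0, 1)")

    caps = dict(params["capacities"])
    caps.update(cap_overrides)
    scen.sah_inhibition_ki = float(params["sah_inhibition_ki"])
    scen.sam_feedback_ki = float(params["sam_feedback_ki"])
    scen.ehna_split = float(params["ehna_split"])

    inf = scen.infected
    kf = scen.knockdown_factor
    if inf:
        for name in ("methyltransferase", "sam_synthetase", "de_novo_purine",
                     "adp_regeneration"):
            caps[name] *= scales[name]
        # L-type transporters are exchangers: induction raises uptake and
        # efflux capacity together, accelerating labeling turnover
        caps["met_uptake"] *= scales["met_transport"]
        caps["met_efflux"] *= scales["met_transport"]
    if scen.genotype == "Ahcy-RNAi":
        caps["ahcy_forward"] *= kf
        caps["ahcy_reverse"] *= kf

    adk3 = params["adk3_share"]
    adk3_eff = adk3 * (scales["adk3"] if inf else 1.0)
    if scen.genotype == "Adk3-RNAi":
        adk3_eff *= kf
    caps["adenosine_kinase"] *= (1.0 - adk3) + adk3_eff

    ak1 = params["ak1_share"]
    ak1_eff = ak1 * (scales["ak1"] if inf else 1.0)
    if scen.genotype == "Ak1-RNAi":
        ak1_eff *= kf
    ak_factor = (1.0 - ak1) + ak1_eff
    caps["adenylate_kinase_fwd"] *= ak_factor
    caps["adenylate_kinase_rev"] *= ak_factor

    caps["adp_regeneration"] *= scen.nutrient_supply

    # media uptake scales with the supplied tracer concentration relative to
    # the concentration the defaults were calibrated at
    if scen.tracer == "Met-13C5":
        caps["met_uptake"] *= scen.tracer_concentration / DEFAULT_TRACER_UM["Met-13C5"]
    if scen.tracer != "Ado-13C5":
        caps["ado_uptake"] = 0.0
    else:
        caps["ado_uptake"] *= scen.tracer_concentration / DEFAULT_TRACER_UM["Ado-13C5"]

    scen.capacities = caps
    amounts = dict(params["pool_amounts"])
    amounts.update(pool_overrides)
    scen.pool_amounts = amounts
    return scen


def _pools(scen: PathwayScenario) -> list[Pool]:
    a = scen.pool_amounts
    return [
        Pool("MetMedium", (), 1.0, buffered=True),
        Pool("AdoMedium", (), 1.0, buffered=True),
        Pool("Met", ("bb", "me"), a["Met"], metabolite="methionine"),
        Pool("SAM", ("bb", "me", "ad"), a["SAM"], metabolite="SAM"),
        Pool("SAH", ("bb", "ad"), a["SAH"], metabolite="SAH"),
        # the instrument cannot reliably detect homocysteine
        Pool("Hcy", ("bb",), a["Hcy"], detectable=False, metabolite="homocysteine"),
        Pool("CTH", ("bb",), a["CTH"], metabolite="cystathionine"),
        Pool("MTA", ("me", "ad"), a["MTA"], metabolite="MTA"),
        Pool("Ado", ("ad",), a["Ado"], metabolite="adenosine"),
        Pool("AdoExtra", ("ad",), 0.0),
        Pool("Ino", ("ad",), 0.0, metabolite="inosine"),
        Pool("AMP", ("ad",), a["AMP"], metabolite="AMP"),
        Pool("ADP", ("ad",), a["ADP"], metabolite="ADP"),
        Pool("ATP", ("ad",), a["ATP"], metabolite="ATP"),
        Pool("IMP", ("ad",), a["IMP"], metabolite="IMP"),
        Pool("R5P", (), a["R5P"], buffered=True),
        Pool("MethylAcceptors", ("me",), 0.0),
        Pool("Polyamines", ("bb",), 0.0),
        Pool("CysSink", ("bb",), 0.0),
    ]


def _met_medium_dist(scen: PathwayScenario, labeled: bool) -> tuple[float, ...]:
    """Labeling of methionine entering from the medium.

    The tracer stock is m+5 (bb+me labeled) with an m+4 impurity whose
    *methyl* carbon is the unlabeled one -- exactly the species that
    remethylation of labeled homocysteine would also produce.
    Met states are ordered (bb bit 0, me bit 1): m+0, m+4, m+1, m+5.
    """
    if not labeled:
        return (1.0, 0.0, 0.0, 0.0)
    q = scen.tracer_impurity
    return (0.0, q, 0.0, 1.0 - q)


def _ado_medium_dist(scen: PathwayScenario, labeled: bool) -> tuple[float, float]:
    # adenosyl is a single 5-carbon unit at moiety resolution, so the stock
    # impurity appears as unlabeled rather than m+4
    if not labeled:
        return (1.0, 0.0)
    q = scen.tracer_impurity
    return (q, 1.0 - q)


def build_network(scen: PathwayScenario, labeled: bool = True) -> PathwayNetwork:
    """Compile the reaction network for a scenario.

    ``labeled=False`` builds the pre-equilibration variant: unlabeled media
    and no medium adenosine (the tracer is only added at the start of the
    ex vivo incubation).
    """
    c = scen.capacities
    ki = scen.sah_inhibition_ki
    ado_cap = c["ado_uptake"] if labeled else 0.0

    reactions = [
        Reaction("met_uptake", c["met_uptake"], ("MetMedium",),
                 consumes={"MetMedium": 1},
                 products=(ProductRule("Met", dist=_met_medium_dist(
                     scen, labeled and scen.tracer == "Met-13C5")),)),
        Reaction("met_efflux", c["met_efflux"], ("Met",), consumes={"Met": 1}),
        # SAM feedback inhibition of its own synthesis (MAT-style)
        Reaction("sam_synthetase", c["sam_synthetase"], ("Met", "ATP"),
                 consumes={"Met": 1, "ATP": 1},
                 products=(ProductRule("SAM", {"bb": ("Met", "bb"),
                                               "me": ("Met", "me"),
                                               "ad": ("ATP", "ad")}),),
                 inhibitor=("SAM", scen.sam_feedback_ki)),
        # SAH product inhibition: accumulated SAH throttles methylation
        Reaction("methyltransferase", c["methyltransferase"], ("SAM",),
                 consumes={"SAM": 1},
                 products=(ProductRule("SAH", {"bb": ("SAM", "bb"),
                                               "ad": ("SAM", "ad")}),
                           ProductRule("MethylAcceptors", {"me": ("SAM", "me")})),
                 inhibitor=("SAH", ki)),
        Reaction("samdc_mta", c["samdc_mta"], ("SAM",), consumes={"SAM": 1},
                 products=(ProductRule("MTA", {"me": ("SAM", "me"),
                                               "ad": ("SAM", "ad")}),
                           ProductRule("Polyamines", {"bb": ("SAM", "bb")}))),
        Reaction("mta_clearance", c["mta_clearance"], ("MTA",),
                 consumes={"MTA": 1}),
        Reaction("ahcy_forward", c["ahcy_forward"], ("SAH",),
                 consumes={"SAH": 1},
                 products=(ProductRule("Hcy", {"bb": ("SAH", "bb")}),
                           ProductRule("Ado", {"ad": ("SAH", "ad")}))),
        Reaction("ahcy_reverse", c["ahcy_reverse"], ("Hcy", "Ado"),
                 consumes={"Hcy": 1, "Ado": 1},
                 products=(ProductRule("SAH", {"bb": ("Hcy", "bb"),
                                               "ad": ("Ado", "ad")}),)),
        # homocysteine remethylation adds an unlabeled methyl: Met m+4
        Reaction("remethylation", c["remethylation"], ("Hcy",),
                 consumes={"Hcy": 1},
                 products=(ProductRule("Met", {"bb": ("Hcy", "bb"),
                                               "me": None}),)),
        Reaction("cbs", c["cbs"], ("Hcy",), consumes={"Hcy": 1},
                 products=(ProductRule("CTH", {"bb": ("Hcy", "bb")}),)),
        Reaction("met_cth_bypass", c["met_cth_bypass"], ("Met",),
                 consumes={"Met": 1},
                 products=(ProductRule("CTH", {"bb": ("Met", "bb")}),)),
        Reaction("cth_clearance", c["cth_clearance"], ("CTH",),
                 consumes={"CTH": 1},
                 products=(ProductRule("CysSink", {"bb": ("CTH", "bb")}),)),
        Reaction("ada", c["ada"], ("Ado",), consumes={"Ado": 1},
                 products=(ProductRule("Ino", {"ad": ("Ado", "ad")}),)),
        Reaction("ent_export", c["ent_export"], ("Ado",), consumes={"Ado": 1},
                 products=(ProductRule("AdoExtra", {"ad": ("Ado", "ad")}),)),
        Reaction("ado_uptake", ado_cap, ("AdoMedium",),
                 consumes={"AdoMedium": 1},
                 products=(ProductRule("Ado", dist=_ado_medium_dist(
                     scen, labeled and scen.tracer == "Ado-13C5")),)),
        Reaction("adenosine_kinase", c["adenosine_kinase"], ("Ado", "ATP"),
                 consumes={"Ado": 1, "ATP": 1},
                 products=(ProductRule("AMP", {"ad": ("Ado", "ad")}),
                           ProductRule("ADP", {"ad": ("ATP", "ad")}))),
        Reaction("adenylate_kinase_fwd", c["adenylate_kinase_fwd"],
                 ("AMP", "ATP"), consumes={"AMP": 1, "ATP": 1},
                 products=(ProductRule("ADP", {"ad": ("AMP", "ad")}),
                           ProductRule("ADP", {"ad": ("ATP", "ad")}))),
        Reaction("adenylate_kinase_rev", c["adenylate_kinase_rev"],
                 ("ADP", "ADP"), consumes={"ADP": 2},
                 products=(ProductRule("AMP", {"ad": ("ADP", "ad")}),
                           ProductRule("ATP", {"ad": ("ADP", "ad")}))),
        Reaction("adp_regeneration", c["adp_regeneration"], ("ADP",),
                 consumes={"ADP": 1},
                 products=(ProductRule("ATP", {"ad": ("ADP", "ad")}),)),
        Reaction("nucleotidase_5p", c["nucleotidase_5p"], ("AMP",),
                 consumes={"AMP": 1},
                 products=(ProductRule("Ado", {"ad": ("AMP", "ad")}),)),
        # lumped de novo purine synthesis: 11 steps, 6 ATP per IMP
        Reaction("de_novo_purine", c["de_novo_purine"], ("R5P", "ATP"),
                 consumes={"R5P": 1, "ATP": 6},
                 products=(ProductRule("IMP", {"ad": None}),
                           ProductRule("ADP", {"ad": ("ATP", "ad")}, stoich=6)),
                 atp_cost=6, step_count=11),
        Reaction("imp_to_amp", c["imp_to_amp"], ("IMP",), consumes={"IMP": 1},
                 products=(ProductRule("AMP", {"ad": ("IMP", "ad")}),)),
    ]
    return PathwayNetwork(_pools(scen), reactions)
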