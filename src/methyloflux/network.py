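"""Curated core network of methylotrophic yeast central metabolism.

This module programmatically builds a desk-scale stoichiometric model of
*Ogataea*-type methanol metabolism together with the three heterologous
product routes studied in the analysis:

* peroxisomal methanol oxidase + catalase,
* xylulose-5-phosphate (XuMP) assimilation of formaldehyde with a lumped
  pentose-phosphate rearrangement block,
* the NADH-generating dissimilatory branch (formaldehyde -> formate -> CO2),
* lower glycolysis, mitochondrial PDH and a full TCA cycle, the cytosolic
  PDH bypass (PDC / ALD / ACS) and ATP-citrate lyase,
* the glyoxylate shunt (isocitrate lyase + malate synthase),
* the cytosolic reductive-TCA malate route (pyruvate carboxylase +
  cytosolic MDH) with a Mae1-style malate exporter,
* the acetone pathway (thiolase, acetoacetyl-CoA hydrolase or CoA
  transferase, acetoacetate decarboxylase),
* the mevalonate pathway to DMAPP plus isoprene synthase,
* respiration at configurable P/O ratios, ATP maintenance, and a lumped
  biomass reaction.

Every non-exchange reaction is elementally balanced over C/H/O/N/P/S;
reduced cofactors carry their hydrogens explicitly (NADH = NAD + H2 etc.)
so that no free-proton bookkeeping is needed.  Carbon skeletons and the
NAD(H)/FAD(H2) pools are compartmentalised (cytosol / mitochondrion /
peroxisome); CO2, O2, H2O and the adenylate pool are modelled as a single
cytosolic pool shared with mitochondrial reactions, a standard core-model
lumping that leaves the carbon and redox accounting untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import (
    MetabolicModel,
    Metabolite,
    Reaction,
    parse_formula,
)

__all__ = [
    "ProductTarget",
    "PRODUCTS",
    "ReactionAliasMap",
    "build_core_model",
    "reference_reaction_aliases",
    "list_subsystems",
]


@dataclass(frozen=True)
class ProductTarget:
    """A methanol-derived product and its yield ceilings.

    The carbon-perfect yield ceiling is ``1/carbon_count`` mol product per
    mol methanol; the electron ceiling is ``6/degree_of_reduction`` because
    methanol carries 6 available electrons per mole.
    """

    name: str
    exchange_reaction: str
    carbon_count: int
    degree_of_reduction: int

    @property
    def carbon_yield_ceiling(self) -> float:
        return 1.0 / self.carbon_count

    @property
    def electron_yield_ceiling(self) -> float:
        return 6.0 / self.degree_of_reduction


#: The three products of the analysis.  Degrees of reduction: malate
#: C4H6O5 -> 12 e-, acetone C3H6O -> 16 e-, isoprene C5H8 -> 28 e-.
PRODUCTS: dict[str, ProductTarget] = {
    "malate": ProductTarget("malate", "EX_mal_e", 4, 12),
    "acetone": ProductTarget("acetone", "EX_act_e", 3, 16),
    "isoprene": ProductTarget("isoprene", "EX_isop_e", 5, 28),
}

METHANOL_EXCHANGE = "EX_meoh_e"
BIOMASS_REACTION = "BIOMASS"
DEFAULT_UPTAKE = 10.0  # mmol/gDW/h methanol uptake used throughout


class ConfigurationError(ValueError):
    """An unknown model-building option was supplied."""


# ---------------------------------------------------------------------------
# metabolite table: id -> (name, compartment, formula)
# ---------------------------------------------------------------------------

_COA = "C21H36N7O16P3S"

_METABOLITES: dict[str, tuple[str, str, str]] = {
    # extracellular
    "meoh_e": ("methanol", "extracellular", "CH4O"),
    "o2_e": ("oxygen", "extracellular", "O2"),
    "co2_e": ("carbon dioxide", "extracellular", "CO2"),
    "h2o_e": ("water", "extracellular", "H2O"),
    "mal_e": ("L-malate", "extracellular", "C4H6O5"),
    "act_e": ("acetone", "extracellular", "C3H6O"),
    "isop_e": ("isoprene", "extracellular", "C5H8"),
    "biomass_e": ("biomass", "extracellular", "C12H22O11"),
    # peroxisome
    "meoh_p": ("methanol", "peroxisome", "CH4O"),
    "o2_p": ("oxygen", "peroxisome", "O2"),
    "fald_p": ("formaldehyde", "peroxisome", "CH2O"),
    "h2o2_p": ("hydrogen peroxide", "peroxisome", "H2O2"),
    "h2o_p": ("water", "peroxisome", "H2O"),
    # cytosol
    "fald_c": ("formaldehyde", "cytosol", "CH2O"),
    "for_c": ("formate", "cytosol", "CH2O2"),
    "xu5p_c": ("xylulose 5-phosphate", "cytosol", "C5H11O8P"),
    "dha_c": ("dihydroxyacetone", "cytosol", "C3H6O3"),
    "dhap_c": ("dihydroxyacetone phosphate", "cytosol", "C3H7O6P"),
    "gap_c": ("glyceraldehyde 3-phosphate", "cytosol", "C3H7O6P"),
    "pyr_c": ("pyruvate", "cytosol", "C3H4O3"),
    "acald_c": ("acetaldehyde", "cytosol", "C2H4O"),
    "ac_c": ("acetate", "cytosol", "C2H4O2"),
    "accoa_c": ("acetyl-CoA", "cytosol", "C23H38N7O17P3S"),
    "coa_c": ("coenzyme A", "cytosol", _COA),
    "oaa_c": ("oxaloacetate", "cytosol", "C4H4O5"),
    "mal_c": ("L-malate", "cytosol", "C4H6O5"),
    "cit_c": ("citrate", "cytosol", "C6H8O7"),
    "icit_c": ("isocitrate", "cytosol", "C6H8O7"),
    "succ_c": ("succinate", "cytosol", "C4H6O4"),
    "glx_c": ("glyoxylate", "cytosol", "C2H2O3"),
    "aacoa_c": ("acetoacetyl-CoA", "cytosol", "C25H40N7O18P3S"),
    "acac_c": ("acetoacetate", "cytosol", "C4H6O3"),
    "act_c": ("acetone", "cytosol", "C3H6O"),
    "hmgcoa_c": ("3-hydroxy-3-methylglutaryl-CoA", "cytosol", "C27H44N7O20P3S"),
    "mev_c": ("mevalonate", "cytosol", "C6H12O4"),
    "ipp_c": ("isopentenyl pyrophosphate", "cytosol", "C5H12O7P2"),
    "dmapp_c": ("dimethylallyl pyrophosphate", "cytosol", "C5H12O7P2"),
    "isop_c": ("isoprene", "cytosol", "C5H8"),
    "ppi_c": ("pyrophosphate", "cytosol", "H4O7P2"),
    "pi_c": ("orthophosphate", "cytosol", "H3O4P"),
    "atp_c": ("ATP", "cytosol", "C10H16N5O13P3"),
    "adp_c": ("ADP", "cytosol", "C10H15N5O10P2"),
    "nad_c": ("NAD+", "cytosol", "C21H27N7O14P2"),
    "nadh_c": ("NADH", "cytosol", "C21H29N7O14P2"),
    "nadp_c": ("NADP+", "cytosol", "C21H28N7O17P3"),
    "nadph_c": ("NADPH", "cytosol", "C21H30N7O17P3"),
    "o2_c": ("oxygen", "cytosol", "O2"),
    "co2_c": ("carbon dioxide", "cytosol", "CO2"),
    "h2o_c": ("water", "cytosol", "H2O"),
    "biomass_c": ("biomass", "cytosol", "C12H22O11"),
    # mitochondrion
    "pyr_m": ("pyruvate", "mitochondrion", "C3H4O3"),
    "accoa_m": ("acetyl-CoA", "mitochondrion", "C23H38N7O17P3S"),
    "coa_m": ("coenzyme A", "mitochondrion", _COA),
    "oaa_m": ("oxaloacetate", "mitochondrion", "C4H4O5"),
    "cit_m": ("citrate", "mitochondrion", "C6H8O7"),
    "icit_m": ("isocitrate", "mitochondrion", "C6H8O7"),
    "akg_m": ("2-oxoglutarate", "mitochondrion", "C5H6O5"),
    "succ_m": ("succinate", "mitochondrion", "C4H6O4"),
    "fum_m": ("fumarate", "mitochondrion", "C4H4O4"),
    "mal_m": ("L-malate", "mitochondrion", "C4H6O5"),
    "nad_m": ("NAD+", "mitochondrion", "C21H27N7O14P2"),
    "nadh_m": ("NADH", "mitochondrion", "C21H29N7O14P2"),
    "fad_m": ("FAD", "mitochondrion", "C27H33N9O15P2"),
    "fadh2_m": ("FADH2", "mitochondrion", "C27H35N9O15P2"),
}


def _rxn(rid: str, name: str, stoich: dict[str, float], subsystem: str,
         lb: float = 0.0, ub: float = 1000.0,
         is_exchange: bool = False) -> Reaction:
    return Reaction(id=rid, name=name, stoich=stoich, lower_bound=lb,
                    upper_bound=ub, subsystem=subsystem,
                    is_exchange=is_exchange)


_VALID_OPTIONS = {
    "uptake", "po_nadh", "po_fadh2", "atp_maintenance", "acetone_variant",
    "include_dissimilation",
}


def build_core_model(
    products: set[str] | None = None,
    **options,
) -> MetabolicModel:
    """Build the core methylotroph model.

    Parameters
    ----------
    products
        Subset of ``{"malate", "acetone", "isoprene"}``; defaults to all
        three.  At least one product is required.
    uptake
        Methanol uptake rate in mmol/gDW/h; sets the methanol exchange
        lower bound to ``-uptake`` (default 10).
    po_nadh, po_fadh2
        P/O ratios of the respiratory chain (defaults 1.5 and 1.0).
    atp_maintenance
        Non-growth ATP maintenance flux (default 0).
    acetone_variant
        ``"hydrolase"`` (acetoacetyl-CoA hydrolase, default) or
        ``"coa_transferase"`` (CtfAB-style, acetate-dependent).
    include_dissimilation
        If False, omit the formaldehyde dissimilatory branch (used in
        what-if analyses; default True).
    """
    unknown = set(options) - _VALID_OPTIONS
    if unknown:
        raise ConfigurationError(f"unknown model options: {sorted(unknown)}")
    uptake = float(options.get("uptake", DEFAULT_UPTAKE))
    po_nadh = float(options.get("po_nadh", 1.5))
    po_fadh2 = float(options.get("po_fadh2", 1.0))
    atpm = float(options.get("atp_maintenance", 0.0))
    acetone_variant = options.get("acetone_variant", "hydrolase")
    if acetone_variant not in ("hydrolase", "coa_transferase"):
        raise ConfigurationError(
            f"acetone_variant must be 'hydrolase' or 'coa_transferase', "
            f"got {acetone_variant!r}")
    include_dissim = bool(options.get("include_dissimilation", True))

    if products is None:
        products = set(PRODUCTS)
    products = set(products)
    if not products:
        raise ConfigurationError("at least one product must be requested")
    unknown_products = products - set(PRODUCTS)
    if unknown_products:
        raise ConfigurationError(f"unknown products: {sorted(unknown_products)}")

    rxns: list[Reaction] = []
    add = rxns.append

    # (1) methanol uptake and peroxisomal oxidation
    add(_rxn("EX_meoh_e", "methanol exchange", {"meoh_e": -1}, "exchange",
             lb=-uptake, ub=0.0, is_exchange=True))
    add(_rxn("MEOHt", "methanol uptake transport", {"meoh_e": -1, "meoh_p": 1},
             "methanol oxidation"))
    add(_rxn("AOX", "methanol oxidase",
             {"meoh_p": -1, "o2_p": -1, "fald_p": 1, "h2o2_p": 1},
             "methanol oxidation"))
    add(_rxn("CAT", "catalase",
             {"h2o2_p": -1, "h2o_p": 1, "o2_p": 0.5}, "methanol oxidation"))
    add(_rxn("FALDtp", "formaldehyde export from peroxisome",
             {"fald_p": -1, "fald_c": 1}, "methanol oxidation"))
    add(_rxn("O2tp", "peroxisomal oxygen transport",
             {"o2_c": -1, "o2_p": 1}, "transport", lb=-1000.0))
    add(_rxn("H2Otp", "peroxisomal water transport",
             {"h2o_p": -1, "h2o_c": 1}, "transport", lb=-1000.0))

    # (2) XuMP assimilation
    add(_rxn("DAS", "dihydroxyacetone synthase",
             {"fald_c": -1, "xu5p_c": -1, "dha_c": 1, "gap_c": 1},
             "xump assimilation"))
    add(_rxn("DAK", "dihydroxyacetone kinase",
             {"dha_c": -1, "atp_c": -1, "dhap_c": 1, "adp_c": 1},
             "xump assimilation"))
    add(_rxn("TPI", "triose-phosphate isomerase",
             {"dhap_c": -1, "gap_c": 1}, "xump assimilation", lb=-1000.0))
    # lumped pentose-phosphate rearrangement: 5 x C3 -> 3 x C5
    add(_rxn("XU5PR", "xylulose-5-phosphate regeneration (lumped PPP block)",
             {"dhap_c": -2, "gap_c": -3, "h2o_c": -2, "xu5p_c": 3, "pi_c": 2},
             "xump assimilation"))

    # (3) dissimilatory branch
    if include_dissim:
        add(_rxn("FALDH", "formaldehyde dehydrogenase (lumped GSH route)",
                 {"fald_c": -1, "nad_c": -1, "h2o_c": -1,
                  "for_c": 1, "nadh_c": 1}, "dissimilation"))
        add(_rxn("FDH", "formate dehydrogenase",
                 {"for_c": -1, "nad_c": -1, "co2_c": 1, "nadh_c": 1},
                 "dissimilation"))

    # (4) lower glycolysis, lumped GAP -> pyruvate
    add(_rxn("GAPPYR", "lower glycolysis (GAP -> pyruvate)",
             {"gap_c": -1, "nad_c": -1, "adp_c": -2, "pi_c": -1,
              "pyr_c": 1, "nadh_c": 1, "atp_c": 2, "h2o_c": 1},
             "lower glycolysis"))

    # cytosolic PDH bypass (PDC / NAD-ALD / ACS)
    add(_rxn("PDC", "pyruvate decarboxylase",
             {"pyr_c": -1, "acald_c": 1, "co2_c": 1}, "pdh bypass"))
    add(_rxn("ALD", "acetaldehyde dehydrogenase (NAD)",
             {"acald_c": -1, "nad_c": -1, "h2o_c": -1,
              "ac_c": 1, "nadh_c": 1}, "pdh bypass"))
    add(_rxn("ACS", "acetyl-CoA synthetase (2 ATP-equivalents)",
             {"ac_c": -1, "coa_c": -1, "atp_c": -2, "h2o_c": -1,
              "accoa_c": 1, "adp_c": 2, "pi_c": 2}, "pdh bypass"))

    # (5) mitochondrial PDH + TCA cycle + citrate export
    add(_rxn("PYRtm", "mitochondrial pyruvate carrier",
             {"pyr_c": -1, "pyr_m": 1}, "transport"))
    add(_rxn("PDHm", "pyruvate dehydrogenase",
             {"pyr_m": -1, "coa_m": -1, "nad_m": -1,
              "accoa_m": 1, "co2_c": 1, "nadh_m": 1}, "tca cycle"))
    add(_rxn("CSm", "citrate synthase",
             {"accoa_m": -1, "oaa_m": -1, "h2o_c": -1,
              "cit_m": 1, "coa_m": 1}, "tca cycle"))
    add(_rxn("ACONm", "aconitase",
             {"cit_m": -1, "icit_m": 1}, "tca cycle", lb=-1000.0))
    add(_rxn("IDHm", "isocitrate dehydrogenase",
             {"icit_m": -1, "nad_m": -1, "akg_m": 1, "co2_c": 1, "nadh_m": 1},
             "tca cycle"))
    add(_rxn("AKGDH", "2-oxoglutarate dehydrogenase + succinyl-CoA synthetase",
             {"akg_m": -1, "nad_m": -1, "adp_c": -1, "pi_c": -1,
              "succ_m": 1, "co2_c": 1, "nadh_m": 1, "atp_c": 1}, "tca cycle"))
    add(_rxn("SDHm", "succinate dehydrogenase",
             {"succ_m": -1, "fad_m": -1, "fum_m": 1, "fadh2_m": 1},
             "tca cycle"))
    add(_rxn("FUMm", "fumarase",
             {"fum_m": -1, "h2o_c": -1, "mal_m": 1}, "tca cycle", lb=-1000.0))
    add(_rxn("MDHm", "mitochondrial malate dehydrogenase",
             {"mal_m": -1, "nad_m": -1, "oaa_m": 1, "nadh_m": 1},
             "tca cycle", lb=-1000.0))
    add(_rxn("CITtam", "mitochondrial citrate exporter",
             {"cit_m": -1, "cit_c": 1}, "transport"))
    add(_rxn("ACL", "ATP-citrate lyase",
             {"cit_c": -1, "coa_c": -1, "atp_c": -1,
              "accoa_c": 1, "oaa_c": 1, "adp_c": 1, "pi_c": 1},
             "citrate lyase"))

    # (6) glyoxylate shunt (cytosolic)
    add(_rxn("ACONc", "cytosolic aconitase",
             {"cit_c": -1, "icit_c": 1}, "glyoxylate shunt", lb=-1000.0))
    add(_rxn("ICL", "isocitrate lyase",
             {"icit_c": -1, "succ_c": 1, "glx_c": 1}, "glyoxylate shunt"))
    add(_rxn("MALS", "malate synthase",
             {"glx_c": -1, "accoa_c": -1, "h2o_c": -1,
              "mal_c": 1, "coa_c": 1}, "glyoxylate shunt"))
    add(_rxn("SUCCtm", "mitochondrial succinate import",
             {"succ_c": -1, "succ_m": 1}, "transport"))

    # (7) cytosolic reductive-TCA malate route
    add(_rxn("PYC", "pyruvate carboxylase",
             {"pyr_c": -1, "co2_c": -1, "atp_c": -1, "h2o_c": -1,
              "oaa_c": 1, "adp_c": 1, "pi_c": 1}, "cytosolic rtca"))
    add(_rxn("MDH", "cytosolic malate dehydrogenase",
             {"oaa_c": -1, "nadh_c": -1, "mal_c": 1, "nad_c": 1},
             "cytosolic rtca", lb=-1000.0))
    add(_rxn("MALtm", "mitochondrial dicarboxylate carrier (malate)",
             {"mal_c": -1, "mal_m": 1}, "transport", lb=-1000.0))

    if "malate" in products:
        add(_rxn("MALt", "malate exporter (Mae1-style)",
                 {"mal_c": -1, "mal_e": 1}, "product transport"))
        add(_rxn("EX_mal_e", "malate exchange", {"mal_e": -1}, "exchange",
                 lb=0.0, ub=1000.0, is_exchange=True))

    # (8) acetone pathway
    if "acetone" in products or "isoprene" in products:
        add(_rxn("THL", "acetyl-CoA acetyltransferase (thiolase)",
                 {"accoa_c": -2, "aacoa_c": 1, "coa_c": 1}, "acetone pathway"))
    if "acetone" in products:
        if acetone_variant == "hydrolase":
            add(_rxn("AACOAH", "acetoacetyl-CoA hydrolase",
                     {"aacoa_c": -1, "h2o_c": -1, "acac_c": 1, "coa_c": 1},
                     "acetone pathway"))
        else:
            add(_rxn("CTFAB", "acetoacetyl-CoA transferase (CtfAB-style)",
                     {"aacoa_c": -1, "ac_c": -1, "acac_c": 1, "accoa_c": 1},
                     "acetone pathway"))
        add(_rxn("ADC", "acetoacetate decarboxylase",
                 {"acac_c": -1, "act_c": 1, "co2_c": 1}, "acetone pathway"))
        add(_rxn("ACTt", "acetone export", {"act_c": -1, "act_e": 1},
                 "product transport"))
        add(_rxn("EX_act_e", "acetone exchange", {"act_e": -1}, "exchange",
                 lb=0.0, ub=1000.0, is_exchange=True))

    # (9) mevalonate pathway + isoprene synthase
    if "isoprene" in products:
        add(_rxn("HMGS", "HMG-CoA synthase",
                 {"aacoa_c": -1, "accoa_c": -1, "h2o_c": -1,
                  "hmgcoa_c": 1, "coa_c": 1}, "mva pathway"))
        add(_rxn("HMGR", "HMG-CoA reductase",
                 {"hmgcoa_c": -1, "nadph_c": -2,
                  "mev_c": 1, "coa_c": 1, "nadp_c": 2}, "mva pathway"))
        add(_rxn("MEVPP", "mevalonate kinases + diphosphomevalonate "
                          "decarboxylase (lumped)",
                 {"mev_c": -1, "atp_c": -3,
                  "ipp_c": 1, "co2_c": 1, "adp_c": 3, "pi_c": 1},
                 "mva pathway"))
        add(_rxn("IDI", "isopentenyl-diphosphate isomerase",
                 {"ipp_c": -1, "dmapp_c": 1}, "mva pathway", lb=-1000.0))
        add(_rxn("ISPS", "isoprene synthase",
                 {"dmapp_c": -1, "isop_c": 1, "ppi_c": 1}, "mva pathway"))
        add(_rxn("PPA", "inorganic pyrophosphatase",
                 {"ppi_c": -1, "h2o_c": -1, "pi_c": 2}, "mva pathway"))
        add(_rxn("ISOPt", "isoprene export", {"isop_c": -1, "isop_e": 1},
                 "product transport"))
        add(_rxn("EX_isop_e", "isoprene exchange", {"isop_e": -1}, "exchange",
                 lb=0.0, ub=1000.0, is_exchange=True))

    # (10) respiration, redox shuttles, maintenance
    add(_rxn("NADHtm", "malate-aspartate shuttle (lumped NADH import)",
             {"nadh_c": -1, "nad_m": -1, "nad_c": 1, "nadh_m": 1},
             "oxidative phosphorylation"))
    add(_rxn("NADHOR", "NADH:O2 oxidoreductase (oxidative phosphorylation)",
             {"nadh_m": -1, "o2_c": -0.5, "adp_c": -po_nadh, "pi_c": -po_nadh,
              "nad_m": 1, "atp_c": po_nadh, "h2o_c": 1.0 + po_nadh},
             "oxidative phosphorylation"))
    add(_rxn("FADHOR", "FADH2:O2 oxidoreductase (oxidative phosphorylation)",
             {"fadh2_m": -1, "o2_c": -0.5, "adp_c": -po_fadh2,
              "pi_c": -po_fadh2,
              "fad_m": 1, "atp_c": po_fadh2, "h2o_c": 1.0 + po_fadh2},
             "oxidative phosphorylation"))
    add(_rxn("THD", "NADPH source (lumped transhydrogenase-like)",
             {"nadh_c": -1, "nadp_c": -1, "nad_c": 1, "nadph_c": 1},
             "oxidative phosphorylation"))
    add(_rxn("ATPM", "non-growth ATP maintenance",
             {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1},
             "maintenance", lb=atpm))

    # (11) biomass: lumped draw on GAP, pyruvate, acetyl-CoA, OAA, ATP,
    # NADPH; the GAP phosphate is returned as Pi since the model has no
    # phosphate exchange (biomass formula C12H22O11)
    add(_rxn("BIOMASS", "biomass (lumped synthetic composition)",
             {"gap_c": -1, "pyr_c": -1, "accoa_c": -1, "oaa_c": -1,
              "atp_c": -30, "nadph_c": -4, "h2o_c": -30,
              "biomass_c": 1, "coa_c": 1, "adp_c": 30, "pi_c": 31,
              "nadp_c": 4}, "biomass"))
    add(_rxn("BIOMASSt", "biomass drain", {"biomass_c": -1, "biomass_e": 1},
             "biomass"))
    add(_rxn("EX_biomass_e", "biomass exchange", {"biomass_e": -1}, "exchange",
             lb=0.0, ub=1000.0, is_exchange=True))

    # gas / water exchanges; CO2 exchange is efflux-only so that methanol is
    # the sole carbon source (the carboxylation route must recycle internal
    # CO2 rather than fix external carbon)
    add(_rxn("O2t", "oxygen transport", {"o2_e": -1, "o2_c": 1},
             "transport", lb=-1000.0))
    add(_rxn("CO2t", "carbon dioxide transport", {"co2_c": -1, "co2_e": 1},
             "transport", lb=-1000.0))
    add(_rxn("H2Ot", "water transport", {"h2o_c": -1, "h2o_e": 1},
             "transport", lb=-1000.0))
    add(_rxn("EX_o2_e", "oxygen exchange", {"o2_e": -1}, "exchange",
             lb=-1000.0, ub=1000.0, is_exchange=True))
    add(_rxn("EX_co2_e", "carbon dioxide exchange", {"co2_e": -1}, "exchange",
             lb=0.0, ub=1000.0, is_exchange=True))
    add(_rxn("EX_h2o_e", "water exchange", {"h2o_e": -1}, "exchange",
             lb=-1000.0, ub=1000.0, is_exchange=True))

    used = {mid for rxn in rxns for mid in rxn.stoich}
    metabolites = [
        Metabolite(id=mid, name=name, compartment=comp,
                   formula=parse_formula(formula))
        for mid, (name, comp, formula) in _METABOLITES.items()
        if mid in used
    ]
    return MetabolicModel(metabolites=metabolites, reactions=rxns,
                          objective=(BIOMASS_REACTION, "maximize"),
                          id="core_methylotroph")


# ---------------------------------------------------------------------------
# reaction aliases used by the pathway-scenario definitions
# ---------------------------------------------------------------------------

UNMAPPED = "<unmapped>"

#: alias -> (core reaction id, merge note or None)
_ALIAS_TABLE: dict[str, tuple[str, str | None]] = {
    "AKGDam": ("AKGDH", "mapped to the lumped AKG dehydrogenase"),
    "AKGDH1+2": ("AKGDH", "both isozymes merged into one lumped reaction"),
    "ICL": ("ICL", None),
    "MDHm": ("MDHm", None),
    "PDHa1": ("PDHm", "single PDH stands in for both isoforms"),
    "PDHcm": ("PDHm", "single PDH stands in for both isoforms"),
    "ACLSm": ("ACL", "single cytosolic ATP-citrate lyase"),
    "CITtam": ("CITtam", None),
    "CITtap": ("CITtam", "peroxisomal citrate carrier merged into the "
                         "single mitochondrial exporter"),
    "CSp+m": ("CSm", "single citrate synthase stands in for both "
                     "compartmental copies"),
    "CSm": ("CSm", None),
    "CSp": ("CSm", "peroxisomal copy merged into the mitochondrial one"),
}


@dataclass
class ReactionAliasMap:
    """Case-insensitive map from scenario reaction aliases to core-model ids.

    Aliases whose distinct counterparts were merged into one core reaction
    carry a documentation note; aliases with no analog resolve to
    :data:`UNMAPPED` rather than being silently dropped.
    """

    mapping: dict[str, str] = field(default_factory=dict)
    notes: dict[str, str] = field(default_factory=dict)

    def resolve(self, alias: str) -> str:
        key = alias.lower()
        table = {a.lower(): rid for a, rid in self.mapping.items()}
        if key not in table:
            return UNMAPPED
        return table[key]

    def __contains__(self, alias: str) -> bool:
        return self.resolve(alias) != UNMAPPED


def reference_reaction_aliases(model: MetabolicModel) -> ReactionAliasMap:
    """Alias map for the bundled core model (total over the scenario set)."""
    mapping: dict[str, str] = {}
    notes: dict[str, str] = {}
    for alias, (rid, note) in _ALIAS_TABLE.items():
        mapping[alias] = rid if model.has_reaction(rid) else UNMAPPED
        if note:
            notes[alias] = note
    return ReactionAliasMap(mapping=mapping, notes=notes)


def list_subsystems(model: MetabolicModel) -> dict[str, list[str]]:
    """Reaction ids grouped by subsystem (pathway block), sorted."""
    groups: dict[str, list[str]] = {}
    for rxn in model.reactions:
        groups.setdefault(rxn.subsystem, []).append(rxn.id)
    return {k: sorted(v) for k, v in sorted(groups.items())}
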