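"""Pinned numerical constants and run configuration.

Every threshold, coefficient and region parameter used by the pipeline lives
here, with its literature source, so that filter definitions are versioned in
one place and can be overridden from a YAML file or the command line.

Sources
-------
- Lipinski CA et al. Adv Drug Deliv Rev 23 (1997) 3-25 (rule of five).
- Ghose AK et al. J Comb Chem 1 (1999) 55-68.
- Veber DF et al. J Med Chem 45 (2002) 2615-2623.
- Egan WJ et al. J Med Chem 43 (2000) 3867-3877 (bounds as used by
  SwissADME: WLOGP <= 5.88, TPSA <= 131.6).
- Muegge I et al. J Med Chem 44 (2001) 1841-1846.
- Teague SJ et al. Angew Chem Int Ed 38 (1999) 3743-3748 (lead-likeness
  window as applied by SwissADME: 250 <= MW <= 350, logP <= 3.5, <= 7
  rotatable bonds).
- Delaney JS. J Chem Inf Comput Sci 44 (2004) 1000-1005 (ESOL).
- Potts RO, Guy RH. Pharm Res 9 (1992) 663-669 (skin permeation).
- Daina A, Zoete V. ChemMedChem 11 (2016) 1117-1121 (BOILED-Egg ellipses).
- Martin YC. J Med Chem 48 (2005) 3164-3170 (Abbott bioavailability score).
- Sander T, Osiris Property Explorer documentation (drug-score sigmoid
  desirabilities and toxicity multipliers).
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, model_validator


class _Frozen(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=False)


# ---------------------------------------------------------------------------
# drug-likeness rule systems
# ---------------------------------------------------------------------------

class LipinskiThresholds(_Frozen):
    mw_max: float = 500.0
    logp_max: float = 5.0
    hba_max: int = 10
    hbd_max: int = 5
    #: a compound passes with at most this many violations
    allowed_violations: int = 1


class GhoseThresholds(_Frozen):
    mw_min: float = 160.0
    mw_max: float = 480.0
    wlogp_min: float = -0.4
    wlogp_max: float = 5.6
    mr_min: float = 40.0
    mr_max: float = 130.0
    atoms_min: int = 20   # total atom count, hydrogens included
    atoms_max: int = 70


class VeberThresholds(_Frozen):
    rotb_max: int = 10
    tpsa_max: float = 140.0


class EganThresholds(_Frozen):
    wlogp_max: float = 5.88
    tpsa_max: float = 131.6


class MueggeThresholds(_Frozen):
    mw_min: float = 200.0
    mw_max: float = 600.0
    logp_min: float = -2.0
    logp_max: float = 5.0
    tpsa_max: float = 150.0
    rings_max: int = 7
    carbons_min: int = 5      # "more than 4 carbons"
    heteroatoms_min: int = 2  # "more than 1 heteroatom"
    rotb_max: int = 15
    hba_max: int = 10
    hbd_max: int = 5


class LeadlikenessThresholds(_Frozen):
    mw_min: float = 250.0
    mw_max: float = 350.0
    logp_max: float = 3.5
    rotb_max: int = 7


class ConsensusRule(_Frozen):
    """How the five rule systems combine into one Y/N drug-likeness call."""
    #: minimum number of passing systems for an overall "Y" (5 = all five)
    min_pass: int = 5


class RuleThresholds(_Frozen):
    lipinski: LipinskiThresholds = LipinskiThresholds()
    ghose: GhoseThresholds = GhoseThresholds()
    veber: VeberThresholds = VeberThresholds()
    egan: EganThresholds = EganThresholds()
    muegge: MueggeThresholds = MueggeThresholds()
    leadlikeness: LeadlikenessThresholds = LeadlikenessThresholds()
    consensus: ConsensusRule = ConsensusRule()


# ---------------------------------------------------------------------------
# solubility / permeation models
# ---------------------------------------------------------------------------

class EsolModel(_Frozen):
    """Delaney's ESOL linear model, logS in log10(mol/L)."""
    intercept: float = 0.16
    coef_clogp: float = -0.63
    coef_mw: float = -0.0062
    coef_rotb: float = 0.066
    coef_aromatic_proportion: float = -0.74
    #: upper logS bound of each class, scanned left to right
    class_bounds: tuple[float, ...] = (-10.0, -6.0, -4.0, -2.0, 0.0)
    class_names: tuple[str, ...] = (
        "insoluble", "poorly soluble", "moderately soluble",
        "soluble", "very soluble", "highly soluble",
    )

    @model_validator(mode="after")
    def _check(self):
        if len(self.class_names) != len(self.class_bounds) + 1:
            raise ValueError("need one more class name than bound")
        if list(self.class_bounds) != sorted(self.class_bounds):
            raise ValueError("class bounds must be increasing")
        return self


class SkinPermeationModel(_Frozen):
    """Potts-Guy form, log Kp in log10(cm/s)."""
    intercept: float = -2.74
    coef_logp: float = 0.71
    coef_mw: float = -0.0061


# ---------------------------------------------------------------------------
# BOILED-Egg regions
# ---------------------------------------------------------------------------

class EllipseSpec(_Frozen):
    """A rotated ellipse in the (TPSA, WLOGP) plane."""
    cx: float
    cy: float
    width: float
    height: float
    angle_deg: float


class EggModel(_Frozen):
    mode: Literal["ellipse", "rectangle"] = "ellipse"
    #: scalar thresholds for rectangle mode (inclusive)
    rect_wlogp_max: float = 5.88
    rect_tpsa_max: float = 131.6
    #: published best-fit ellipses (Daina & Zoete 2016)
    white: EllipseSpec = EllipseSpec(
        cx=71.051, cy=2.292, width=142.081, height=8.740, angle_deg=-1.031325)
    yolk: EllipseSpec = EllipseSpec(
        cx=38.117, cy=3.177, width=82.061, height=5.557, angle_deg=-0.171887)


# ---------------------------------------------------------------------------
# OSIRIS-style drug score
# ---------------------------------------------------------------------------

class DrugScoreModel(_Frozen):
    """Desirability product for the overall drug score.

    Each continuous property p contributes 0.5 + 0.5 / (1 + exp(a*p + b));
    each toxicity endpoint contributes a level multiplier. The result lies
    in (0, 1].
    """
    # (a, b) pairs of the sigmoid 1 / (1 + exp(a*p + b))
    clogp_ab: tuple[float, float] = (1.0, -5.0)          # s(cLogP - 5)
    logs_ab: tuple[float, float] = (-1.0, -5.0)          # s(-logS - 5)
    mw_ab: tuple[float, float] = (0.012, -6.0)           # s(0.012 MW - 6)
    druglikeness_ab: tuple[float, float] = (-1.0, 0.0)   # s(-DL)
    toxicity_multipliers: dict[str, float] = {
        "none": 1.0, "medium": 0.8, "high": 0.6,
    }


# ---------------------------------------------------------------------------
# bioavailability score (Martin)
# ---------------------------------------------------------------------------

class BioavailabilityModel(_Frozen):
    #: anionic compounds are binned on TPSA
    anion_tpsa_high: float = 150.0   # TPSA > 150 -> 0.11
    anion_tpsa_mid: float = 75.0     # 75 < TPSA <= 150 -> 0.56, else 0.85
    score_anion_high_tpsa: float = 0.11
    score_anion_mid_tpsa: float = 0.56
    score_anion_low_tpsa: float = 0.85
    score_neutral_pass: float = 0.55
    score_neutral_fail: float = 0.17


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

class PipelineConfig(_Frozen):
    """Everything a pipeline run needs; CLI flags override file values."""
    roster_path: Optional[str] = None        # None -> packaged collection
    score_table_path: Optional[str] = None   # None -> packaged appendix table
    include_standards: bool = True
    egg_mode: Literal["ellipse", "rectangle"] = "ellipse"
    k: int = 3
    seed: int = 0
    output_dir: str = "avnscreen-out"
    report_formats: tuple[str, ...] = ("json", "csv")

    rules: RuleThresholds = RuleThresholds()
    esol: EsolModel = EsolModel()
    skin: SkinPermeationModel = SkinPermeationModel()
    egg: EggModel = EggModel()
    drug_score: DrugScoreModel = DrugScoreModel()
    bioavailability: BioavailabilityModel = BioavailabilityModel()

    @model_validator(mode="after")
    def _check(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        return self


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from an optional YAML file.

    Unknown keys in the file are rejected. Keyword overrides win over file
    values, which win over the defaults above.
    """
    data: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**data)


DEFAULT_CONFIG = PipelineConfig()
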