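"""Drug-likeness rule systems, lead-likeness and the bioavailability score.

Five threshold systems (Lipinski, Ghose, Veber, Egan, Muegge) each return a
:class:`RuleVerdict` carrying named violations. Lipinski tolerates one
violation; the others none. All bounds are inclusive at equality, matching
the source publications' "less than or equal" phrasing. Thresholds are
pinned in :mod:`avnscreen.config`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import DEFAULT_CONFIG, RuleThresholds, BioavailabilityModel
from .descriptors import DescriptorSet

SYSTEMS = ("lipinski", "ghose", "veber", "egan", "muegge")


@dataclass
class RuleVerdict:
    system: str
    passed: bool
    violations: list[str] = field(default_factory=list)

    @property
    def n_violations(self) -> int:
        return len(self.violations)


def _verdict(system: str, violations: list[str], allowed: int = 0) -> RuleVerdict:
    return RuleVerdict(system=system, passed=len(violations) <= allowed,
                       violations=violations)


def lipinski(d: DescriptorSet, thresholds: RuleThresholds | None = None) -> RuleVerdict:
    """Rule of five; a compound passes with at most one violation."""
    t = (thresholds or DEFAULT_CONFIG.rules).lipinski
    v = []
    if d.mw > t.mw_max:
        v.append(f"MW>{t.mw_max:g}")
    if d.consensus_logp > t.logp_max:
        v.append(f"logP>{t.logp_max:g}")
    if d.hba > t.hba_max:
        v.append(f"HBA>{t.hba_max}")
    if d.hbd > t.hbd_max:
        v.append(f"HBD>{t.hbd_max}")
    return _verdict("lipinski", v, allowed=t.allowed_violations)


def ghose(d: DescriptorSet, thresholds: RuleThresholds | None = None) -> RuleVerdict:
    t = (thresholds or DEFAULT_CONFIG.rules).ghose
    v = []
    if not t.mw_min <= d.mw <= t.mw_max:
        v.append("MW")
    if not t.wlogp_min <= d.wlogp <= t.wlogp_max:
        v.append("WLOGP")
    if not t.mr_min <= d.molar_refractivity <= t.mr_max:
        v.append("MR")
    if not t.atoms_min <= d.n_atoms_total <= t.atoms_max:
        v.append("atoms")
    return _verdict("ghose", v)


def veber(d: DescriptorSet, thresholds: RuleThresholds | None = None) -> RuleVerdict:
    t = (thresholds or DEFAULT_CONFIG.rules).veber
    v = []
    if d.n_rotatable > t.rotb_max:
        v.append(f"RotB>{t.rotb_max}")
    if d.tpsa > t.tpsa_max:
        v.append(f"TPSA>{t.tpsa_max:g}")
    return _verdict("veber", v)


def egan(d: DescriptorSet, thresholds: RuleThresholds | None = None) -> RuleVerdict:
    t = (thresholds or DEFAULT_CONFIG.rules).egan
    v = []
    if d.wlogp > t.wlogp_max:
        v.append(f"WLOGP>{t.wlogp_max:g}")
    if d.tpsa > t.tpsa_max:
        v.append(f"TPSA>{t.tpsa_max:g}")
    return _verdict("egan", v)


def muegge(d: DescriptorSet, thresholds: RuleThresholds | None = None) -> RuleVerdict:
    t = (thresholds or DEFAULT_CONFIG.rules).muegge
    v = []
    if not t.mw_min <= d.mw <= t.mw_max:
        v.append("MW")
    if not t.logp_min <= d.consensus_logp <= t.logp_max:
        v.append("logP")
    if d.tpsa > t.tpsa_max:
        v.append("TPSA")
    if d.n_rings > t.rings_max:
        v.append("rings")
    if d.n_carbons < t.carbons_min:
        v.append("carbons")
    if d.n_heteroatoms < t.heteroatoms_min:
        v.append("heteroatoms")
    if d.n_rotatable > t.rotb_max:
        v.append("RotB")
    if d.hba > t.hba_max:
        v.append("HBA")
    if d.hbd > t.hbd_max:
        v.append("HBD")
    return _verdict("muegge", v)


def all_five(d: DescriptorSet, thresholds: RuleThresholds | None = None
             ) -> dict[str, RuleVerdict]:
    return {
        "lipinski": lipinski(d, thresholds),
        "ghose": ghose(d, thresholds),
        "veber": veber(d, thresholds),
        "egan": egan(d, thresholds),
        "muegge": muegge(d, thresholds),
    }


def druglikeness_consensus(verdicts: dict[str, RuleVerdict],
                           min_pass: int | None = None) -> tuple[int, str]:
    """Combine the five rule verdicts into ``(n_pass, 'Y'/'N')``.

    The default requires all five systems to pass; ``min_pass`` relaxes
    this to a >=k-of-5 rule.
    """
    missing = [s for s in SYSTEMS if s not in verdicts]
    if missing:
        raise ValueError(f"missing rule verdicts: {missing}")
    if min_pass is None:
        min_pass = DEFAULT_CONFIG.rules.consensus.min_pass
    n_pass = sum(1 for s in SYSTEMS if verdicts[s].passed)
    return n_pass, ("Y" if n_pass >= min_pass else "N")


def leadlikeness(d: DescriptorSet, external_logp: float | None = None,
                 thresholds: RuleThresholds | None = None) -> str:
    """Lead-likeness Y/N: 250 <= MW <= 350, logP <= 3.5, <= 7 rotatable
    bonds. ``external_logp`` (e.g. an ingested XLOGP3 column) takes
    precedence over the internal consensus estimate when provided."""
    t = (thresholds or DEFAULT_CONFIG.rules).leadlikeness
    logp = external_logp if external_logp is not None else d.consensus_logp
    ok = (t.mw_min <= d.mw <= t.mw_max
          and logp <= t.logp_max
          and d.n_rotatable <= t.rotb_max)
    return "Y" if ok else "N"


def bioavailability_score(d: DescriptorSet,
                          charge_class: str | None = None,
                          model: BioavailabilityModel | None = None,
                          thresholds: RuleThresholds | None = None) -> float:
    """Abbott bioavailability score (probability-like, rule based).

    ``charge_class`` is ``"anion"`` or ``"neutral"``; when omitted it is
    inferred from the presence of a carboxylic acid (all roster members are
    neutral carboxylic acids, treated as anions at physiological pH).
    """
    m = model or DEFAULT_CONFIG.bioavailability
    if charge_class is None:
        charge_class = "anion" if d.has_carboxylic_acid else "neutral"
    if charge_class == "anion":
        if d.tpsa > m.anion_tpsa_high:
            return m.score_anion_high_tpsa
        if d.tpsa > m.anion_tpsa_mid:
            return m.score_anion_mid_tpsa
        return m.score_anion_low_tpsa
    return (m.score_neutral_pass
            if lipinski(d, thresholds).passed else m.score_neutral_fail)
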