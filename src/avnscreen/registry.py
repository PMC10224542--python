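"""Compound registry: scaffolds, the avenanthramide collection, roster I/O
and synthetic stand-in score tables.

Avenanthramides (AVNs) are amides of an anthranilate-derived ring ("ring A")
and a hydroxycinnamate-derived ring ("ring B") joined by an acyl linker with
zero, one or two E-configured double bonds. The study collection is stored as
a substituent grid: each compound code maps to a scaffold plus a position ->
{H, OH, OCH3} map on the two rings.

Code convention (the established AVN shorthand): the leading digit encodes
the anthranilate ring pattern (1 = unsubstituted, 2 = 5-OH, 3 = 4-OH,
4 = 4-OCH3/5-OH, 5 = 4,5-diOH), the letter encodes the cinnamoyl part
(a = cinnamoyl, p = p-coumaroyl 4-OH, c = caffeoyl 3,4-diOH, f = feruloyl
4-OH/3-OCH3, s = sinapoyl 4-OH/3,5-diOCH3, m = 4-OCH3, h = other mono-OH
positional isomers) and a trailing "d" marks the two-double-bond (avenalumic)
scaffold.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator
from rdkit import Chem

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """Bad scaffold/substituent specification."""


class RosterError(ValueError):
    """Bad roster or grid file content."""


# ---------------------------------------------------------------------------
# scaffolds
# ---------------------------------------------------------------------------

#: labelled attachment positions: four on ring A (anthranilate numbering
#: C3-C6; C1 carries the carboxylic acid, C2 the amide nitrogen) and four on
#: ring B (cinnamate numbering C2-C5 relative to the linker attachment).
RING_A_POSITIONS = ("A3", "A4", "A5", "A6")
RING_B_POSITIONS = ("B2", "B3", "B4", "B5")
POSITIONS = RING_A_POSITIONS + RING_B_POSITIONS

#: substituent tokens -> SMILES branch text
SUBSTITUENT_SMILES = {"H": "", "OH": "(O)", "OCH3": "(OC)"}


@dataclass(frozen=True)
class ScaffoldSpec:
    """One of the three AVN cores.

    ``linker_smiles`` is the acyl bridge between the amide nitrogen and
    ring B; double bonds are fixed E, and no other stereocentres exist.
    """
    scaffold_id: str
    linker_smiles: str
    linker_double_bonds: int

    def core_smiles(self) -> str:
        return _assemble(self, {})

    def core_pattern(self) -> Chem.Mol:
        """Substructure query for the unsubstituted core (ignoring stereo)."""
        smi = Chem.MolToSmiles(Chem.MolFromSmiles(self.core_smiles()))
        q = Chem.MolFromSmarts(Chem.MolToSmiles(
            Chem.MolFromSmiles(smi), isomericSmiles=False))
        return q


SCAFFOLDS: dict[str, ScaffoldSpec] = {
    "monoene": ScaffoldSpec("monoene", "/C=C/", 1),
    "diene": ScaffoldSpec("diene", "/C=C/C=C/", 2),
    "dihydro_monoene": ScaffoldSpec("dihydro_monoene", "CC", 0),
}


def _assemble(scaffold: ScaffoldSpec, subs: Mapping[str, str]) -> str:
    toks = {}
    for pos in POSITIONS:
        val = subs.get(pos, "H")
        if val not in SUBSTITUENT_SMILES:
            raise ConfigurationError(
                f"invalid substituent {val!r} at {pos}; "
                f"expected one of {sorted(SUBSTITUENT_SMILES)}")
        toks[pos] = SUBSTITUENT_SMILES[val]
    return (
        "OC(=O)c1c{A6}c{A5}c{A4}c{A3}c1NC(=O)"
        "{link}c2c{B2}c{B3}c{B4}c{B5}c2"
    ).format(link=scaffold.linker_smiles, **toks)


def build_structure(scaffold: str | ScaffoldSpec,
                    substituents: Mapping[str, str] | None = None) -> str:
    """Assemble a canonical SMILES for a scaffold + substituent map.

    Parameters
    ----------
    scaffold : scaffold id or :class:`ScaffoldSpec`
    substituents : mapping of position label (A3..A6, B2..B5) to one of
        ``H``, ``OH``, ``OCH3``. Missing positions default to H.

    Returns
    -------
    str : RDKit canonical isomeric SMILES. Re-canonicalising the result is
    a no-op, so the output is duplicate-stable.
    """
    if isinstance(scaffold, str):
        try:
            scaffold = SCAFFOLDS[scaffold]
        except KeyError:
            raise ConfigurationError(f"unknown scaffold {scaffold!r}") from None
    substituents = dict(substituents or {})
    for pos in substituents:
        if pos not in POSITIONS:
            raise ConfigurationError(
                f"unknown attachment position {pos!r}; expected one of "
                f"{POSITIONS}")
    smi = _assemble(scaffold, substituents)
    mol = Chem.MolFromSmiles(smi)
    if mol is None:  # pragma: no cover - template guarantees parseability
        raise ConfigurationError(f"assembled structure failed to parse: {smi}")
    return Chem.MolToSmiles(mol)


# ---------------------------------------------------------------------------
# compound entries and the packaged collection
# ---------------------------------------------------------------------------

@dataclass
class CompoundEntry:
    """One roster member."""
    code: str
    scaffold_id: str
    substituents: dict[str, str] = field(default_factory=dict)
    smiles: str = ""
    name: str = ""
    is_standard: bool = False

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:
            raise RosterError(f"entry {self.code!r}: unparseable SMILES")
        return m


_GRID_RESOURCE = "avn_collection_synthetic.csv"
_SCORES_RESOURCE = "appendix_scores_synthetic.csv"


def _packaged(name: str) -> Path:
    return Path(resources.files("avnscreen").joinpath("data", name))


def default_grid_path() -> Path:
    """Packaged study-collection grid (reconstruction; see module docs)."""
    return _packaged(_GRID_RESOURCE)


def default_score_table_path() -> Path:
    """Packaged external-predictor score table (synthetic reconstruction)."""
    return _packaged(_SCORES_RESOURCE)


def enumerate_collection(grid_file: str | Path | None = None,
                         include_standards: bool = True) -> list[CompoundEntry]:
    """Load the compound collection from a substituent grid CSV.

    The grid has columns ``code, name, scaffold, A3..A6, B2..B5, standard,
    smiles``; an explicit ``smiles`` value, when present, must agree with the
    structure assembled from the grid columns. Duplicate codes or duplicate
    canonical structures are load errors.
    """
    path = Path(grid_file) if grid_file is not None else default_grid_path()
    if not path.exists():
        raise RosterError(f"grid file not found: {path}")
    entries: list[CompoundEntry] = []
    seen_codes: set[str] = set()
    seen_smiles: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.DictReader(_skip_comments(fh))]
    for i, row in enumerate(rows, start=2):
        code = (row.get("code") or "").strip()
        if not code:
            raise RosterError(f"{path}: row {i}: missing code")
        if code in seen_codes:
            raise RosterError(f"{path}: duplicate code {code!r}")
        seen_codes.add(code)
        scaffold = (row.get("scaffold") or "").strip()
        if scaffold not in SCAFFOLDS:
            raise RosterError(
                f"{path}: entry {code!r}: unknown scaffold {scaffold!r}")
        subs = {}
        for pos in POSITIONS:
            val = (row.get(pos) or "H").strip() or "H"
            if val != "H":
                subs[pos] = val
        try:
            can = build_structure(scaffold, subs)
        except ConfigurationError as exc:
            raise RosterError(f"{path}: entry {code!r}: {exc}") from exc
        explicit = (row.get("smiles") or "").strip()
        if explicit:
            m = Chem.MolFromSmiles(explicit)
            if m is None:
                raise RosterError(
                    f"{path}: entry {code!r}: unparseable explicit SMILES")
            if Chem.MolToSmiles(m) != can:
                raise RosterError(
                    f"{path}: entry {code!r}: explicit SMILES disagrees with "
                    f"grid-assembled structure")
        if can in seen_smiles:
            raise RosterError(
                f"{path}: entry {code!r} duplicates the structure of "
                f"{seen_smiles[can]!r}")
        seen_smiles[can] = code
        entries.append(CompoundEntry(
            code=code,
            scaffold_id=scaffold,
            substituents=subs,
            smiles=can,
            name=(row.get("name") or "").strip(),
            is_standard=(row.get("standard") or "").strip() in ("1", "Y", "yes"),
        ))
    if not include_standards:
        entries = [e for e in entries if not e.is_standard]
    logger.info("loaded %d compounds from %s", len(entries), path)
    return entries


def _skip_comments(fh: Iterable[str]) -> Iterable[str]:
    for line in fh:
        if not line.lstrip().startswith("#"):
            yield line


# ---------------------------------------------------------------------------
# roster I/O
# ---------------------------------------------------------------------------

_ROSTER_FORMATS = ("smiles", "sdf", "csv")


def write_roster(entries: Iterable[CompoundEntry], path: str | Path,
                 fmt: str | None = None) -> None:
    """Write a roster as a tab-separated SMILES list, V2000 SDF or CSV."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    fmt = {"smi": "smiles"}.get(fmt, fmt)
    if fmt not in _ROSTER_FORMATS:
        raise RosterError(f"unknown roster format {fmt!r}")
    entries = list(entries)
    if fmt == "smiles":
        with open(path, "w", encoding="utf-8") as fh:
            for e in entries:
                fh.write(f"{e.smiles}\t{e.code}\n")
    elif fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["code", "scaffold", *POSITIONS, "standard", "name",
                        "smiles"])
            for e in entries:
                w.writerow([e.code, e.scaffold_id,
                            *[e.substituents.get(p, "H") for p in POSITIONS],
                            int(e.is_standard), e.name, e.smiles])
    else:  # sdf
        writer = Chem.SDWriter(str(path))
        writer.SetForceV3000(False)
        try:
            for e in entries:
                m = e.mol()
                m.SetProp("_Name", e.code)
                m.SetProp("code", e.code)
                m.SetProp("scaffold", e.scaffold_id)
                m.SetProp("standard", str(int(e.is_standard)))
                if e.name:
                    m.SetProp("name", e.name)
                for p, v in e.substituents.items():
                    m.SetProp(f"sub_{p}", v)
                writer.write(m)
        finally:
            writer.close()


def read_roster(path: str | Path, fmt: str | None = None) -> list[CompoundEntry]:
    """Read a roster written by :func:`write_roster`.

    Round trip preserves codes and canonical structures. Malformed records
    raise :class:`RosterError` naming the offending line or record.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    fmt = {"smi": "smiles"}.get(fmt, fmt)
    if fmt not in _ROSTER_FORMATS:
        raise RosterError(f"unknown roster format {fmt!r}")
    entries: list[CompoundEntry] = []
    if fmt == "smiles":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                smi = parts[0]
                code = parts[1] if len(parts) > 1 else f"line{lineno}"
                m = Chem.MolFromSmiles(smi)
                if m is None:
                    raise RosterError(
                        f"{path}: line {lineno}: unparseable SMILES {smi!r}")
                entries.append(CompoundEntry(
                    code=code, scaffold_id=_infer_scaffold(m),
                    smiles=Chem.MolToSmiles(m)))
    elif fmt == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            for i, row in enumerate(csv.DictReader(_skip_comments(fh)), start=2):
                smi = (row.get("smiles") or "").strip()
                m = Chem.MolFromSmiles(smi)
                if m is None:
                    raise RosterError(f"{path}: row {i}: unparseable SMILES")
                subs = {p: row[p] for p in POSITIONS
                        if row.get(p) and row[p] != "H"}
                entries.append(CompoundEntry(
                    code=row["code"], scaffold_id=row.get("scaffold", ""),
                    substituents=subs, smiles=Chem.MolToSmiles(m),
                    name=row.get("name", ""),
                    is_standard=row.get("standard", "0") in ("1", "Y", "yes")))
    else:  # sdf
        supplier = Chem.SDMolSupplier(str(path))
        for idx, m in enumerate(supplier):
            if m is None:
                raise RosterError(f"{path}: record {idx}: unparseable molecule")
            code = m.GetProp("code") if m.HasProp("code") else m.GetProp("_Name")
            subs = {}
            for prop in m.GetPropNames():
                if prop.startswith("sub_"):
                    subs[prop[4:]] = m.GetProp(prop)
            entries.append(CompoundEntry(
                code=code,
                scaffold_id=(m.GetProp("scaffold")
                             if m.HasProp("scaffold") else _infer_scaffold(m)),
                substituents=subs,
                smiles=Chem.MolToSmiles(m),
                name=m.GetProp("name") if m.HasProp("name") else "",
                is_standard=(m.GetProp("standard") == "1"
                             if m.HasProp("standard") else False)))
    codes = [e.code for e in entries]
    if len(set(codes)) != len(codes):
        raise RosterError(f"{path}: duplicate codes in roster")
    return entries


def _infer_scaffold(mol: Chem.Mol) -> str:
    for sid in ("diene", "monoene", "dihydro_monoene"):
        if mol.HasSubstructMatch(SCAFFOLDS[sid].core_pattern()):
            return sid
    return ""


# ---------------------------------------------------------------------------
# score tables (external predictor columns, real or synthetic)
# ---------------------------------------------------------------------------

BIOACTIVITY_COLUMNS = ("GPCRL", "ICHM", "KI", "NRL", "PI", "EI")
TOXICITY_COLUMNS = ("tox_mutagenic", "tox_tumorigenic",
                    "tox_irritant", "tox_reproductive")
TOXICITY_LEVELS = ("none", "medium", "high")


def read_score_table(path: str | Path | None = None) -> pd.DataFrame:
    """Read a per-compound score table (CSV/TSV), keyed by ``code``.

    The Unicode minus (U+2212), as copied from typeset tables, is normalised
    to the ASCII hyphen-minus before numeric parsing. Comment lines starting
    with ``#`` (e.g. a recorded seed) are skipped.
    """
    path = Path(path) if path is not None else default_score_table_path()
    text = Path(path).read_text(encoding="utf-8").replace("−", "-")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, comment="#")
    if "code" not in df.columns:
        raise RosterError(f"{path}: score table lacks a 'code' column")
    if df["code"].duplicated().any():
        dups = df.loc[df["code"].duplicated(), "code"].tolist()
        raise RosterError(f"{path}: duplicate codes {dups}")
    return df.set_index("code", drop=False)


class SyntheticScoreConfig(BaseModel):
    """Distributional description of a synthetic stand-in score table.

    Defaults emulate the external predictors' output ranges seen in the
    study: the six bioactivity category scores sit mostly in [-1, 0.5],
    drug scores in (0, 1), OSIRIS drug-likeness is a wide, roughly centred
    value, and toxicity endpoints are mostly benign.
    """
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    bioactivity_range: tuple[float, float] = (-1.0, 0.5)
    drug_score_range: tuple[float, float] = (0.1, 0.9)
    druglikeness_mean_sd: tuple[float, float] = (0.0, 2.0)
    toxicity_level_probs: dict[str, float] = {
        "none": 0.7, "medium": 0.2, "high": 0.1,
    }
    clogp_range: tuple[float, float] = (0.5, 3.5)
    logs_range: tuple[float, float] = (-5.0, -2.0)
    leadlike_prob: float = 0.5

    @model_validator(mode="after")
    def _check(self):
        for name in ("bioactivity_range", "drug_score_range",
                     "clogp_range", "logs_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered")
        if set(self.toxicity_level_probs) != set(TOXICITY_LEVELS):
            raise ValueError(f"toxicity probs must cover {TOXICITY_LEVELS}")
        if abs(sum(self.toxicity_level_probs.values()) - 1.0) > 1e-9:
            raise ValueError("toxicity probabilities must sum to 1")
        if not 0.0 <= self.leadlike_prob <= 1.0:
            raise ValueError("leadlike_prob must be a probability")
        return self


def generate_synthetic_scores(cfg: SyntheticScoreConfig,
                              codes: list[str]) -> pd.DataFrame:
    """Draw a seeded synthetic score table for the given compound codes.

    One row per code; the six bioactivity columns are i.i.d. uniform over
    ``bioactivity_range``, the drug score uniform over ``drug_score_range``,
    drug-likeness normal, toxicity levels categorical, and lead-likeness
    Bernoulli. Identical seeds give identical tables.
    """
    if not codes:
        raise ValueError("codes must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    n = len(codes)
    data: dict[str, object] = {"code": list(codes)}
    lo, hi = cfg.bioactivity_range
    for col in BIOACTIVITY_COLUMNS:
        data[col] = rng.uniform(lo, hi, size=n)
    data["osiris_clogp"] = rng.uniform(*cfg.clogp_range, size=n)
    data["osiris_logs"] = rng.uniform(*cfg.logs_range, size=n)
    mean, sd = cfg.druglikeness_mean_sd
    data["druglikeness"] = rng.normal(mean, sd, size=n)
    data["drug_score"] = rng.uniform(*cfg.drug_score_range, size=n)
    levels = list(TOXICITY_LEVELS)
    probs = [cfg.toxicity_level_probs[l] for l in levels]
    for col in TOXICITY_COLUMNS:
        data[col] = rng.choice(levels, size=n, p=probs)
    data["leadlikeness"] = np.where(
        rng.random(size=n) < cfg.leadlike_prob, "Y", "N")
    df = pd.DataFrame(data).set_index("code", drop=False)
    df.attrs["seed"] = cfg.seed
    return df


def write_score_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a score table as CSV, recording the seed in a header comment."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if "seed" in df.attrs:
            fh.write(f"# seed={df.attrs['seed']}\n")
        df.to_csv(fh, index=False)
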