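"""Structural alert screening against the PAINS and Brenk catalogs.

The published pattern collections (Baell-Holloway PAINS; Brenk unwanted
functionality) are used as curated and distributed with RDKit's
FilterCatalog; compiling the catalog validates every pattern. A compound
matching one alert several times collapses to a single named hit with the
match count recorded, since the workflow counts alert types, not sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from rdkit import Chem
from rdkit.Chem import FilterCatalog

CATALOG_NAMES = ("PAINS", "BRENK")


@dataclass(frozen=True)
class AlertHit:
    code: str
    catalog: str
    alert_name: str
    n_matches: int


class AlertCatalog:
    """A compiled, named substructure-alert catalog."""

    def __init__(self, name: str, catalog: FilterCatalog.FilterCatalog):
        self.name = name
        self._catalog = catalog

    @property
    def alert_names(self) -> list[str]:
        return sorted(self._catalog.GetEntryWithIdx(i).GetDescription()
                      for i in range(self._catalog.GetNumEntries()))

    def matches(self, mol: Chem.Mol) -> dict[str, int]:
        """Alert name -> number of distinct substructure matches."""
        out: dict[str, int] = {}
        for entry in self._catalog.GetMatches(mol):
            name = entry.GetDescription()
            n = 0
            for fm in entry.GetFilterMatches(mol):
                n += 1
            out[name] = max(out.get(name, 0), n or 1)
        return out


def load_catalog(name: str) -> AlertCatalog:
    """Load and compile a published alert catalog by name (PAINS, BRENK)."""
    key = name.upper()
    if key not in CATALOG_NAMES:
        raise ValueError(f"unknown alert catalog {name!r}; "
                         f"expected one of {CATALOG_NAMES}")
    params = FilterCatalog.FilterCatalogParams()
    params.AddCatalog(getattr(FilterCatalog.FilterCatalogParams.FilterCatalogs, key))
    cat = FilterCatalog.FilterCatalog(params)
    if cat.GetNumEntries() == 0:  # pragma: no cover - shipped catalogs
        raise ValueError(f"catalog {name!r} compiled empty")
    return AlertCatalog(key, cat)


def screen(mol: Chem.Mol | str, catalog: AlertCatalog,
           code: str = "") -> list[AlertHit]:
    """Screen one molecule; one hit per matched alert name, sorted by name."""
    if isinstance(mol, str):
        m = Chem.MolFromSmiles(mol)
        if m is None:
            raise ValueError(f"unparseable SMILES: {mol!r}")
        mol = m
    hits = [AlertHit(code=code, catalog=catalog.name, alert_name=k, n_matches=v)
            for k, v in catalog.matches(mol).items()]
    return sorted(hits, key=lambda h: h.alert_name)


def alert_summary(entries: Iterable, catalogs: Iterable[AlertCatalog]
                  ) -> pd.DataFrame:
    """Per-compound alert table over a roster.

    One row per (code, catalog, alert); additionally exposes per-compound
    totals via ``df.attrs["counts"]`` as a (code x catalog) count table.
    """
    catalogs = list(catalogs)
    rows = []
    counts: dict[str, dict[str, int]] = {}
    for e in entries:
        mol = e.mol()
        counts[e.code] = {}
        for cat in catalogs:
            hits = screen(mol, cat, code=e.code)
            counts[e.code][cat.name] = len(hits)
            for h in hits:
                rows.append({"code": h.code, "catalog": h.catalog,
                             "alert_name": h.alert_name,
                             "n_matches": h.n_matches})
    df = pd.DataFrame(rows, columns=["code", "catalog", "alert_name",
                                     "n_matches"])
    df.attrs["counts"] = pd.DataFrame(counts).T.fillna(0).astype(int)
    return df
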