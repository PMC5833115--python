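"""Reading, coding, and coverage-filtering of trait / environment / gene tables and trees.

Trait tables are species x trait grids coded ``+`` (growth), ``-`` (no growth),
``v`` (variable among assayed strains), ``n`` (no data).  In memory a coded
table is a :class:`pandas.DataFrame` of the canonical code strings
(``present``/``absent``/``variable``/``missing``); after the variable rule it
becomes a float frame with values ``1.0``/``0.0`` and ``NaN`` for missing.
"""

from __future__ import annotations

import logging
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

log = logging.getLogger("traitnet")

PRESENT = "present"
ABSENT = "absent"
VARIABLE = "variable"
MISSING = "missing"

#: token synonyms accepted in coded trait tables (case-insensitive)
DEFAULT_TOKENS = {
    "+": PRESENT, "1": PRESENT, "p": PRESENT,
    "-": ABSENT, "−": ABSENT, "0": ABSENT,
    "v": VARIABLE,
    "n": MISSING, "na": MISSING, "?": MISSING, "": MISSING,
}

CODES = (PRESENT, ABSENT, VARIABLE, MISSING)

#: environments with fewer member species than this are ineligible for testing
MIN_ENVIRONMENT_SPECIES = 4


class TraitTableError(ValueError):
    """Malformed trait/environment table (duplicates, bad tokens, shape)."""


def _check_unique(ids, kind: str) -> None:
    counts = pd.Index(ids).value_counts()
    dups = counts[counts > 1]
    if len(dups):
        raise TraitTableError(f"duplicate {kind} id(s): {', '.join(map(str, dups.index))}")


def _read_frame(path, dialect: str | None) -> pd.DataFrame:
    path = Path(path)
    if dialect is None:
        dialect = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=dialect, index_col=0, dtype=str, keep_default_na=False)
    _check_unique(df.index, "species")
    _check_unique(df.columns, "trait/column")
    return df


def read_trait_table(path, dialect: str | None = None, tokens=None) -> pd.DataFrame:
    """Read a coded species x trait table into canonical codes.

    Parameters
    ----------
    path : str or Path
        TSV/CSV file; header row of trait ids, first column species ids.
    dialect : str, optional
        Field delimiter; inferred from the suffix when omitted.
    tokens : mapping, optional
        Cell-token synonym map; defaults to ``+/-/v/n`` plus ``1/0/NA``.

    Returns
    -------
    pandas.DataFrame
        Values in ``{present, absent, variable, missing}``, input order kept.
    """
    tokens = dict(DEFAULT_TOKENS if tokens is None else tokens)
    df = _read_frame(path, dialect)
    out = df.copy()
    for j, col in enumerate(df.columns):
        mapped = df[col].str.strip().str.lower().map(tokens)
        bad = mapped.isna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise TraitTableError(
                f"unrecognized cell token {df[col].iloc[i]!r} at species "
                f"{df.index[i]!r} (row {i + 1}), trait {col!r} (column {j + 1})"
            )
        out[col] = mapped
    return out


def write_trait_table(df: pd.DataFrame, path, dialect: str = "\t") -> None:
    """Write a coded table back to ``+/-/v/n`` tokens (round-trip partner)."""
    rev = {PRESENT: "+", ABSENT: "-", VARIABLE: "v", MISSING: "n"}
    df.replace(rev).to_csv(path, sep=dialect)


def apply_variable_rule(raw: pd.DataFrame) -> pd.DataFrame:
    """Convert codes to numbers, scoring variable growth as positive.

    A trait scored "variable" means only some assayed strains of the species
    grew; such cells are treated as presence (1).  Missing stays ``NaN``.
    """
    mapping = {PRESENT: 1.0, VARIABLE: 1.0, ABSENT: 0.0, MISSING: np.nan}
    bad = ~raw.isin(list(mapping)).all()
    if bad.any():
        raise TraitTableError(f"non-code cells in columns: {list(raw.columns[bad])}")
    return pd.DataFrame(
        np.vectorize(mapping.get)(raw.to_numpy(dtype=object)).astype(float),
        index=raw.index, columns=raw.columns,
    )


def filter_by_coverage(
    m: pd.DataFrame, trait_min: float = 0.8, species_min: float = 0.2
) -> pd.DataFrame:
    """Drop poorly observed traits, then poorly observed species.

    A trait must be observed (non-missing) in at least ``trait_min`` of the
    species; afterwards a species must have data for at least ``species_min``
    of the remaining traits.  Dropped ids are logged.
    """
    if not (0 < trait_min <= 1 and 0 < species_min <= 1):
        raise ValueError("coverage fractions must be in (0, 1]")
    obs = m.notna()
    keep_traits = obs.mean(axis=0) >= trait_min
    dropped_traits = list(m.columns[~keep_traits])
    m2 = m.loc[:, keep_traits]
    if m2.shape[1] == 0:
        raise TraitTableError("no traits left after coverage filtering")
    keep_species = m2.notna().mean(axis=1) >= species_min
    dropped_species = list(m2.index[~keep_species])
    m2 = m2.loc[keep_species]
    if m2.shape[0] == 0:
        raise TraitTableError("no species left after coverage filtering")
    if dropped_traits:
        log.info("coverage filter dropped %d trait(s): %s", len(dropped_traits), dropped_traits)
    if dropped_species:
        log.info("coverage filter dropped %d species: %s", len(dropped_species), dropped_species)
    return m2


def read_environment_table(path, dialect: str | None = None) -> pd.DataFrame:
    """Read a binary species x environment table.

    Returns an int frame; use :func:`eligible_environments` for the
    four-or-more-species rule.  Non-binary cells are an error.
    """
    df = _read_frame(path, dialect)
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=int)
    for j, col in enumerate(df.columns):
        vals = df[col].str.strip()
        ok = vals.isin(["0", "1"])
        if not ok.all():
            i = int(np.flatnonzero(~ok.to_numpy())[0])
            raise TraitTableError(
                f"non-binary cell {df[col].iloc[i]!r} at species {df.index[i]!r} "
                f"(row {i + 1}), environment {col!r} (column {j + 1})"
            )
        out[col] = vals.astype(int)
    for env, n in out.sum(axis=0).items():
        if n == 0:
            log.warning("environment %r has no member species", env)
    return out


def eligible_environments(env: pd.DataFrame, min_species: int = MIN_ENVIRONMENT_SPECIES) -> pd.Series:
    """Boolean per environment: has at least ``min_species`` member species."""
    return env.sum(axis=0) >= min_species


def read_gene_table(path, dialect: str | None = None) -> pd.DataFrame:
    """Binary species x column table of gene presence and growth phenotypes."""
    return read_environment_table(path, dialect)


def write_binary_table(df: pd.DataFrame, path, dialect: str = "\t") -> None:
    df.astype(int).to_csv(path, sep=dialect)


def normalize_label(label: str) -> str:
    """Whitespace/underscore normalization used to match tree tips to species ids."""
    return " ".join(str(label).replace("_", " ").split())


def read_tree(path, species_ids=None) -> dendropy.Tree:
    """Parse a rooted newick tree; optionally check tips cover ``species_ids``.

    Tip labels are compared after underscore/whitespace normalization.
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    if species_ids is not None:
        tips = {normalize_label(t.taxon.label) for t in tree.leaf_node_iter()}
        wanted = {normalize_label(s) for s in species_ids}
        missing = wanted - tips
        if missing:
            log.warning("%d species absent from the tree (dropped in tree-based analyses)", len(missing))
    return tree
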