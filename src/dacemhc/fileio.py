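"""Tabular and tree file formats used by the pipeline.

All coordinates are 0-based half-open internally; dashes in count tables
are read as zero counts.  TSV outputs carry a header comment with the
package version and a configuration digest so runs can be matched to their
parameters.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import AlleleCatalog
from .divstats import AlleleCountTable, StatError


class TableFormatError(ValueError):
    pass


def config_digest(payload: str | Mapping) -> str:
    if not isinstance(payload, str):
        import json

        payload = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def write_tsv(df: pd.DataFrame, path: str | Path, digest: str = "") -> None:
    with open(path, "w") as fh:
        from . import __version__

        fh.write(f"# dacemhc {__version__} config={digest or 'none'}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# allele count tables (site x allele copy counts)
# ---------------------------------------------------------------------------

def load_counts_table(path: str | Path) -> AlleleCountTable:
    """Read a site x allele counts TSV.

    Layout: columns ``site``, ``river``, ``position``, one column per
    allele, and optionally ``total``.  Dash characters read as zero.  When
    a ``total`` column is present each row sum is validated against it.
    """
    df = _read_table(path)
    for c in AlleleCountTable.META_COLS:
        if c not in df.columns:
            raise TableFormatError(f"counts table {path} lacks column {c!r}")
    allele_cols = [c for c in df.columns
                   if c not in AlleleCountTable.META_COLS and c.lower() != "total"]
    for c in allele_cols:
        df[c] = (df[c].fillna("0").replace({"-": "0", "–": "0", "": "0"})
                 .astype(int))
    total_col = next((c for c in df.columns if c.lower() == "total"), None)
    if total_col is not None:
        totals = df[total_col].astype(int)
        sums = df[allele_cols].sum(axis=1)
        bad = df.loc[totals != sums, "site"].tolist()
        if bad:
            raise TableFormatError(
                f"row sum does not match the stated total for site(s) {bad}")
        df = df.drop(columns=[total_col])
    return AlleleCountTable(df)


def write_counts_table(table: AlleleCountTable, path: str | Path,
                       digest: str = "") -> None:
    df = table.df.copy()
    df["total"] = df[list(table.allele_columns)].sum(axis=1)
    write_tsv(df, path, digest)


def bundled_counts_table() -> AlleleCountTable:
    """The published site x allele copy-count table for the six MHC-typed
    longnose dace sampling sites (three rivers, upstream/downstream)."""
    path = Path(__file__).parent / "data" / "mhc_allele_counts.tsv"
    return load_counts_table(path)


# ---------------------------------------------------------------------------
# site metadata and distance matrices
# ---------------------------------------------------------------------------

def load_site_metadata(path: str | Path) -> pd.DataFrame:
    df = _read_table(path)
    for c in ("site", "river", "position"):
        if c not in df.columns:
            raise TableFormatError(f"site metadata lacks column {c!r}")
    return df


def load_distance_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Labeled square TSV matrix -> (labels, ndarray)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if list(df.index) != list(df.columns):
        raise TableFormatError(f"{path}: row and column labels differ")
    return list(df.index), df.to_numpy(dtype=float)


def write_distance_matrix(labels: Sequence[str], m: np.ndarray,
                          path: str | Path, digest: str = "") -> None:
    df = pd.DataFrame(np.asarray(m), index=list(labels), columns=list(labels))
    with open(path, "w") as fh:
        from . import __version__

        fh.write(f"# dacemhc {__version__} config={digest or 'none'}\n")
        df.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# genotype tables and trees
# ---------------------------------------------------------------------------

def write_genotype_table(table, path: str | Path, digest: str = "") -> None:
    write_tsv(table.to_dataframe(), path, digest)


def read_genotype_table(path: str | Path):
    from .genotyper import GenotypeRow, GenotypeTable

    df = _read_table(path).fillna("")
    rows = []
    for _, r in df.iterrows():
        alleles = tuple(a for a in str(r["alleles"]).split(",") if a)
        fracs = [float(x) for x in str(r["fractions"]).split(",") if x]
        rows.append(GenotypeRow(r["individual_id"], r["site"] or None, alleles,
                                dict(zip(alleles, fracs)), r["flag"],
                                r.get("replicate_of") or None))
    return GenotypeTable(rows)


def write_newick(newick: str, path: str | Path) -> None:
    text = newick.strip()
    if not text.endswith(";"):
        text += ";"
    Path(path).write_text(text + "\n")


def counts_from_genotypes(table, catalog: AlleleCatalog,
                          site_meta: pd.DataFrame) -> AlleleCountTable:
    """Aggregate called genotypes into a site x allele copy-count table.

    Only rows flagged ok contribute; a homozygote contributes two copies of
    its single allele.
    """
    meta = {r["site"]: (r["river"], r["position"])
            for _, r in site_meta.iterrows()}
    records = []
    sites = sorted({row.site_code for row in table if row.site_code})
    for site in sites:
        if site not in meta:
            raise TableFormatError(f"site {site!r} missing from metadata")
        counts = dict.fromkeys(catalog.ids, 0)
        for row in table:
            if row.site_code != site or row.flag != "ok":
                continue
            alleles = list(row.called_alleles)
            if len(alleles) == 1:
                alleles = alleles * 2
            for a in alleles:
                counts[a] += 1
        river, position = meta[site]
        records.append({"site": site, "river": river, "position": position,
                        **counts})
    return AlleleCountTable(pd.DataFrame(records))
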