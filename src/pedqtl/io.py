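"""Table readers/writers and cross-validation of the input bundle.

All interchange is plain CSV/TSV: pedigree (``id,sire,dam,sex,generation``),
genetic map (``marker,chrom,pos_cm``), genotypes (rows = individuals, first
column ``id``, one column per marker, values 0/1/2 or a missing token) and
phenotypes/covariates (first column ``id``).  Missing tokens ``NA``, ``-``
and the empty field are normalized everywhere.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import Pedigree, validate_pedigree
from .scan import GenomeMap, GenotypeData

__all__ = [
    "read_pedigree",
    "read_map",
    "read_genotypes",
    "read_phenotypes",
    "read_tables",
    "write_genotypes",
    "write_identity",
    "write_provenance",
]

_NA = ["NA", "na", "-", ""]


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    need = {"id", "sire", "dam"}
    missing = need - {c.lower() for c in df.columns}
    if missing:
        raise ValueError(f"pedigree file {path} is missing column(s): {sorted(missing)}")
    return validate_pedigree(df)


def read_map(path) -> GenomeMap:
    return GenomeMap(pd.read_csv(path))


def read_genotypes(path, gmap: GenomeMap | None = None) -> GenotypeData:
    df = pd.read_csv(path, na_values=_NA, keep_default_na=True)
    idcol = df.columns[0]
    ids = df[idcol].astype(str).tolist()
    df = df.drop(columns=[idcol])
    markers = [str(c) for c in df.columns]
    if gmap is not None:
        extra = [m for m in markers if m not in set(gmap.markers)]
        if extra:
            raise ValueError(f"genotype marker(s) absent from the map: {extra}")
        # reorder columns to map order, keeping only typed markers
        markers = [m for m in gmap.markers if m in set(markers)]
        df = df[markers]
    return GenotypeData(ids, markers, df.to_numpy(float))


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=_NA, keep_default_na=True)
    df[df.columns[0]] = df[df.columns[0]].astype(str)
    return df.rename(columns={df.columns[0]: "id"})


def read_tables(pedigree_path, map_path, genotype_path, phenotype_path):
    """Read and cross-validate the four input tables.

    Checks: phenotype ids are pedigree members; genotype markers appear in
    the map (and are reordered to map order); genotype ids are pedigree
    members.  Returns ``(Pedigree, GenomeMap, GenotypeData, phenotypes)``.
    """
    ped = read_pedigree(pedigree_path)
    gmap = read_map(map_path)
    geno = read_genotypes(genotype_path, gmap)
    phen = read_phenotypes(phenotype_path)
    known = set(ped.ids)
    bad = sorted(set(phen["id"]) - known)
    if bad:
        raise ValueError(f"phenotype id(s) not in pedigree: {bad}")
    bad = sorted(set(geno.ids) - known)
    if bad:
        raise ValueError(f"genotyped id(s) not in pedigree: {bad}")
    return ped, gmap, geno, phen


def write_genotypes(gd: GenotypeData, path):
    gd.to_frame().rename_axis("id").to_csv(path, na_rep="NA")


def write_identity(ic, delta_path, f_path):
    """Long-format identity coefficient tables (TSV)."""
    ic.to_frame().to_csv(delta_path, sep="\t", index=False)
    ic.f_frame().to_csv(f_path, sep="\t", index=False)


def write_provenance(path, seed, config: dict):
    """Record the exact run configuration next to every output."""
    import pedqtl

    payload = {
        "package": "pedqtl",
        "version": getattr(pedqtl, "__version__", "unknown"),
        "seed": seed,
        "config": {k: (str(v) if isinstance(v, Path) else v) for k, v in config.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return payload
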