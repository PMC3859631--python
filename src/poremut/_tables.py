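"""Packaged reference tables (element radii, max-ASA, residue properties)."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("poremut.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)


@lru_cache(maxsize=None)
def vdw_radii() -> dict[str, float]:
    """van der Waals radius (Å) per element symbol."""
    df = _read_packaged("vdw_radii.tsv")
    return {e.upper(): float(r) for e, r in zip(df["element"], df["radius_A"])}


@lru_cache(maxsize=None)
def max_asa(reference: str = "tien_theoretical") -> dict[str, float]:
    """Maximum accessible surface area (Å², Gly-X-Gly reference) per residue.

    ``reference`` selects the column: ``tien_theoretical`` (default) or
    ``miller``.
    """
    df = _read_packaged("max_asa.tsv")
    if reference not in df.columns:
        raise KeyError(f"unknown max-ASA reference table {reference!r}")
    return {r: float(v) for r, v in zip(df["res_name"], df[reference])}


@lru_cache(maxsize=None)
def aa_properties() -> pd.DataFrame:
    """Residue volume (Å³), polarity class and charge class for the 20 standard AAs."""
    df = _read_packaged("aa_properties.tsv")
    df = df.assign(volume_A3=df["volume_A3"].astype(float))
    return df.set_index("res_name")
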