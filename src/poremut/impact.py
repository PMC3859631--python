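"""Missense-mutation impact classification.

A substitution is scored on three residue-level properties — side-chain
volume change (destabilizing when |ΔV| >= 30 Å³), charge-class change
(negative / neutral / positive, His counted positive) and polarity-class
change over the three-way nonpolar / polar / very-polar partition — plus the
structural context: buriedness (RSA < 15%), localization (dimer interface,
ion pathway, near-interface, surface, buried elsewhere, or outside the
modelled range) and side-chain contacts lost in the mutant.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from poremut._tables import STANDARD_AA, aa_properties
from poremut.contacts import AROMATIC_RESIDUES, Contact, contacts_lost, detect_aromatic, detect_hbonds
from poremut.interface import InterfaceSet, near_interface
from poremut.pore import PoreLining
from poremut.structure import AnalysisConfig, Structure
from poremut.surface import RsaRecord, relative_sasa, shrake_rupley

VOLUME_DESTABILIZING_A3 = 30.0  # inclusive threshold on |delta volume|

LOCALIZATIONS = (
    "interface", "pore", "near_interface", "surface", "buried_other", "outside_model",
)


class AAPropertyTable:
    """Volume, polarity class and charge class per 3-letter residue code."""

    def __init__(self, frame: pd.DataFrame | None = None) -> None:
        self._df = frame if frame is not None else aa_properties()
        missing = STANDARD_AA - set(self._df.index)
        if missing:
            raise ValueError(f"property table missing residues: {sorted(missing)}")

    def _row(self, code: str):
        code = code.upper()
        if code not in self._df.index:
            raise KeyError(f"unknown residue code {code!r}")
        return self._df.loc[code]

    def volume(self, code: str) -> float:
        return float(self._row(code)["volume_A3"])

    def polarity_class(self, code: str) -> str:
        return str(self._row(code)["polarity_class"])

    def charge_class(self, code: str) -> str:
        return str(self._row(code)["charge_class"])


_HGVS_P = re.compile(r"p\.\(?([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})\)?$")


@dataclass(frozen=True)
class Mutation:
    position: int
    wt: str
    mut: str
    label: str = ""

    def __post_init__(self) -> None:
        for code in (self.wt, self.mut):
            if code.upper() not in STANDARD_AA:
                raise ValueError(f"non-standard residue code {code!r}")
        if self.wt.upper() == self.mut.upper():
            raise ValueError("wild-type and mutant residues are identical")
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if not self.label:
            object.__setattr__(
                self, "label",
                f"p.({self.wt.capitalize()}{self.position}{self.mut.capitalize()})",
            )

    @classmethod
    def from_hgvs(cls, label: str) -> "Mutation":
        m = _HGVS_P.match(label.strip())
        if not m or m.group(1).upper() not in STANDARD_AA or m.group(3).upper() not in STANDARD_AA:
            raise ValueError(f"unsupported protein HGVS string {label!r}")
        return cls(int(m.group(2)), m.group(1).upper(), m.group(3).upper(), label.strip())


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (matches printed tabular values like +30 from +30.2)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def delta_volume(wt: str, mut: str, table: AAPropertyTable | None = None) -> float:
    """Side-chain volume change volume(mut) - volume(wt) in Å³ (full precision)."""
    table = table or AAPropertyTable()
    return table.volume(mut) - table.volume(wt)


def volume_destabilizing(delta: float) -> bool:
    """|ΔV| >= 30 Å³ counts as destabilizing (boundary inclusive)."""
    return abs(delta) >= VOLUME_DESTABILIZING_A3


def charge_change(wt: str, mut: str, table: AAPropertyTable | None = None) -> bool:
    table = table or AAPropertyTable()
    return table.charge_class(wt) != table.charge_class(mut)


def polarity_change(wt: str, mut: str, table: AAPropertyTable | None = None) -> bool:
    table = table or AAPropertyTable()
    return table.polarity_class(wt) != table.polarity_class(mut)


@dataclass
class MutationImpactReport:
    mutation: Mutation
    delta_volume: float
    volume_destabilizing: bool
    charge_change: bool
    polarity_change: bool
    rsa: float | None  # None <=> outside model
    buried: bool | None
    localization: str
    contacts: list[Contact] = field(default_factory=list)
    contacts_lost: list[Contact] = field(default_factory=list)
    in_excluded_region: bool = False
    note: str = ""

    @property
    def triple(self) -> str:
        """Compact '±N/Yes|No/Yes|No' rendering of ΔV/charge/polarity."""
        dv = int(round_half_away(self.delta_volume))
        sign = "+" if dv > 0 else ""
        return (f"{sign}{dv}/"
                f"{'Yes' if self.charge_change else 'No'}/"
                f"{'Yes' if self.polarity_change else 'No'}")

    def to_dict(self) -> dict:
        return {
            "label": self.mutation.label,
            "position": self.mutation.position,
            "wt": self.mutation.wt,
            "mut": self.mutation.mut,
            "delta_volume_A3": round_half_away(self.delta_volume),
            "volume_destabilizing": self.volume_destabilizing,
            "charge_change": self.charge_change,
            "polarity_change": self.polarity_change,
            "rsa_pct": "outside model" if self.rsa is None else self.rsa,
            "buried": self.buried,
            "localization": self.localization,
            "triple": self.triple,
            "contacts": [c.detail for c in self.contacts],
            "contacts_lost": [c.detail for c in self.contacts_lost],
            "note": self.note,
        }


def classify_localization(mutation: Mutation, interface: InterfaceSet | None,
                          lining: PoreLining | None, rsa_records: list[RsaRecord],
                          model_range: tuple[int, int],
                          structure: Structure | None = None,
                          chain_id: str = "A",
                          near_cutoff: float = 6.0) -> str:
    """Localization class with fixed precedence.

    outside_model > interface > pore > near_interface > buried_other > surface.
    The near-interface check needs geometry, so it is skipped when no
    structure is supplied.
    """
    pos = mutation.position
    if not (model_range[0] <= pos <= model_range[1]):
        return "outside_model"
    key = (chain_id, pos, "")
    if interface is not None and key in interface:
        return "interface"
    if lining is not None and key in lining.residues:
        return "pore"
    if (structure is not None and interface is not None
            and len(structure.chain_ids) >= 2
            and near_interface(key, structure, cutoff=near_cutoff, interface=interface)):
        return "near_interface"
    rec = next((r for r in rsa_records if r.key == key), None)
    if rec is not None and rec.buried:
        return "buried_other"
    return "surface"


def annotate_mutation(mutation: Mutation, structure: Structure,
                      interface: InterfaceSet | None, lining: PoreLining | None,
                      config: AnalysisConfig | None = None,
                      chain_id: str = "A",
                      model_range: tuple[int, int] | None = None,
                      rsa_records: list[RsaRecord] | None = None,
                      table: AAPropertyTable | None = None) -> MutationImpactReport:
    """Full per-mutation report on one chain of the structure.

    ΔV/charge/polarity are always computed; exposed positions keep the values
    but are flagged so the caller knows the buried-residue rationale does not
    apply. Positions outside ``model_range`` carry no structural annotation.
    """
    config = config or AnalysisConfig()
    table = table or AAPropertyTable()
    dv = delta_volume(mutation.wt, mutation.mut, table)
    base = dict(
        mutation=mutation,
        delta_volume=dv,
        volume_destabilizing=volume_destabilizing(dv),
        charge_change=charge_change(mutation.wt, mutation.mut, table),
        polarity_change=polarity_change(mutation.wt, mutation.mut, table),
    )
    if model_range is None:
        seqs = [r.res_seq for r in structure.chain(chain_id)]
        model_range = (min(seqs), max(seqs))
    if not (model_range[0] <= mutation.position <= model_range[1]):
        return MutationImpactReport(**base, rsa=None, buried=None,
                                    localization="outside_model",
                                    note="outside modelled range")
    res = structure.get_residue(chain_id, mutation.position)
    if res.res_name != mutation.wt.upper():
        raise ValueError(
            f"wild-type mismatch at {chain_id}/{mutation.position}: "
            f"expected {mutation.wt.upper()}, structure has {res.res_name}"
        )
    if rsa_records is None:
        rsa_records = relative_sasa(shrake_rupley(structure, config), structure)
    rec = next((r for r in rsa_records if r.key == res.key), None)
    contacts = detect_hbonds(structure, res.key)
    if res.res_name in AROMATIC_RESIDUES:
        contacts = contacts + detect_aromatic(structure, res.key)
    lost = contacts_lost(contacts, mutation.mut)
    loc = classify_localization(mutation, interface, lining, rsa_records,
                                model_range, structure, chain_id)
    excluded = config.is_excluded(res.key)
    note = ""
    if excluded:
        note = "in excluded (disordered) region - not analysed in detail"
    elif rec is not None and rec.buried is False:
        note = "surface - structural-change rules not applied"
    return MutationImpactReport(
        **base,
        rsa=None if rec is None else rec.rsa,
        buried=None if rec is None else rec.buried,
        localization=loc,
        contacts=contacts,
        contacts_lost=lost,
        in_excluded_region=excluded,
        note=note,
    )


def tabulate_effect_correlation(reports: list[MutationImpactReport],
                                functional_annotations: dict[str, str]) -> pd.DataFrame:
    """Counts of functional-effect classes within each localization class.

    ``functional_annotations`` maps mutation label to one of
    ``pronounced_DN`` / ``weak_DN`` / ``no_DN``.
    """
    missing = [r.mutation.label for r in reports if r.mutation.label not in functional_annotations]
    if missing:
        raise KeyError(f"missing functional annotation for: {', '.join(missing)}")
    effects = ["pronounced_DN", "weak_DN", "no_DN"]
    out = pd.DataFrame(0, index=list(LOCALIZATIONS), columns=effects)
    for r in reports:
        eff = functional_annotations[r.mutation.label]
        if eff not in effects:
            raise ValueError(f"unknown effect class {eff!r}")
        out.loc[r.localization, eff] += 1
    return out


def load_reference_mutations() -> pd.DataFrame:
    """Packaged transcription of the published interface/pathway/novel mutation tables.

    Columns include the printed RSA, ΔV/charge/polarity triple, contact
    strings, functional-effect class and a ``divergence`` marker for the rows
    whose printed values cannot be reproduced from any standard residue-volume
    set (probable errata in the source tables).
    """
    with resources.files("poremut.data").joinpath("table23_mutations.tsv").open("r") as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    df["position"] = df["position"].astype(int)
    return df
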