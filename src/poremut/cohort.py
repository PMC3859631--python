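"""Cohort variant tables: HGVS-style parsing, phased allele counting, summaries.

Patients carry one or two disease alleles; an allele may hold several cis
variants. The allele denominator is 2 per proband except probands with a
single detected variant, which contribute 1 (their second allele is
unresolved). A mutation's allele count is the number of allele groups
containing it, so homozygotes contribute 2 and each member of a cis pair
credits its own mutation once.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from poremut.impact import round_half_away

VARIANT_CLASSES = (
    "missense", "nonsense", "frameshift", "splice", "inframe_del", "large_del", "other",
)

PHENOTYPES = ("TD", "BD", "MC_isolated")


@dataclass(frozen=True)
class VariantRecord:
    cdna: str
    protein: str = ""
    variant_class: str = "other"
    novel: bool = False

    def format(self) -> str:
        """Canonical rendering; round-trips the supported grammar."""
        return f"{self.cdna}, {self.protein}" if self.protein else self.cdna


@dataclass
class PatientRecord:
    patient_id: str
    phenotype: str
    alleles: list[list[VariantRecord]]

    def __post_init__(self) -> None:
        total = sum(len(g) for g in self.alleles)
        if not (1 <= total <= 3):
            raise ValueError(f"patient {self.patient_id}: {total} variants (expected 1-3)")
        if not (1 <= len(self.alleles) <= 2):
            raise ValueError(f"patient {self.patient_id}: {len(self.alleles)} allele groups")
        if len(self.alleles) == 1 and total != 1:
            raise ValueError(
                f"patient {self.patient_id}: one allele group only allowed for a single variant"
            )
        if any(not g for g in self.alleles):
            raise ValueError(f"patient {self.patient_id}: empty allele group")

    def variants(self) -> list[VariantRecord]:
        return [v for g in self.alleles for v in g]


@dataclass
class CohortSummary:
    n_patients: int
    n_disease_alleles: int
    allele_counts: dict[str, int]  # keyed by cdna
    percentages: dict[str, float]  # one decimal, half-away rounding
    protein_labels: dict[str, str]  # cdna -> protein label (when any)
    n_distinct_mutations: int
    novel: dict[str, int]

    def percent_for(self, label: str) -> float:
        """Percentage by cdna or protein label."""
        if label in self.percentages:
            return self.percentages[label]
        for cdna, prot in self.protein_labels.items():
            if prot == label:
                return self.percentages[cdna]
        raise KeyError(f"no mutation {label!r} in cohort")

    def count_for(self, label: str) -> int:
        if label in self.allele_counts:
            return self.allele_counts[label]
        for cdna, prot in self.protein_labels.items():
            if prot == label:
                return self.allele_counts[cdna]
        raise KeyError(f"no mutation {label!r} in cohort")


# ---------------------------------------------------------------------------
# HGVS-like parsing
# ---------------------------------------------------------------------------

_SUB = re.compile(r"^c\.(\d+)([+-]\d+)?([ACGT])>([ACGT])$")
_DEL = re.compile(r"^c\.(\d+)(?:([_-])(\d+))?del([ACGT]*)$")
_DELINS = re.compile(r"^c\.(\d+)(?:_(\d+))?delins([ACGT]+)$")

_P_MISSENSE = re.compile(r"^p\.\(?([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})\)?$")
_P_NONSENSE = re.compile(r"^p\.\(?([A-Z][a-z]{2})(\d+)(\*|Ter)\)?$")


def _classify_protein(protein: str) -> str | None:
    p = protein.strip()
    if not p:
        return None
    if "fs" in p:
        return "frameshift"
    if _P_NONSENSE.match(p):
        return "nonsense"
    if _P_MISSENSE.match(p):
        return "missense"
    return None


def parse_variant(cdna: str, protein: str = "", novel: bool = False,
                  large_del: bool = False) -> VariantRecord:
    """Parse a cDNA/protein HGVS pair into a classified :class:`VariantRecord`.

    Supported cDNA grammar: substitutions ``c.N[+/-M]X>Y``, deletions
    ``c.N_Mdel[XX]`` / ``c.NdelX`` and delins ``c.N_MdelinsXX``. A hyphen
    between two coordinates is read as a range separator only when the second
    number exceeds the first by more than 100 (otherwise it is an intronic
    offset); such forms are normalised to the underscore spelling.
    """
    cdna = cdna.strip()
    protein = protein.strip()
    intronic = False
    norm = cdna
    if (m := _SUB.match(cdna)):
        intronic = m.group(2) is not None
    elif (m := _DEL.match(cdna)):
        if m.group(2) == "-":
            start, end = int(m.group(1)), int(m.group(3))
            if end - start > 100:
                norm = f"c.{start}_{end}del{m.group(4)}"
            else:
                intronic = True
    elif _DELINS.match(cdna):
        pass
    else:
        raise ValueError(f"unparseable cDNA variant {cdna!r}")
    if large_del:
        vclass = "large_del"
    else:
        vclass = _classify_protein(protein)
        if vclass is None:
            vclass = "splice" if intronic else (
                "inframe_del" if "del" in norm and "ins" not in norm else "other"
            )
    if intronic and vclass == "other":
        vclass = "splice"
    return VariantRecord(norm, protein, vclass, novel)


# ---------------------------------------------------------------------------
# Cohort table I/O
# ---------------------------------------------------------------------------

def _truthy(s: str) -> bool:
    return str(s).strip().lower() in ("yes", "true", "1", "y")


def load_cohort(path) -> list[PatientRecord]:
    """Read the cohort TSV (patient_id, phenotype, vN_cdna/protein/novel, phase).

    The phase column groups variants into alleles ("1|1|2" = variants 1 and 2
    cis on allele 1). Three-variant patients without a phase default to the
    two most-5' variants cis, with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        raise ValueError(f"{path}: empty cohort table")
    required = {"patient_id", "phenotype", "v1_cdna"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    patients: list[PatientRecord] = []
    for _, row in df.iterrows():
        variants: list[VariantRecord] = []
        positions: list[int] = []
        for i in (1, 2, 3):
            cdna = str(row.get(f"v{i}_cdna", "")).strip()
            if not cdna:
                continue
            v = parse_variant(cdna, str(row.get(f"v{i}_protein", "")),
                              _truthy(row.get(f"v{i}_novel", "")))
            variants.append(v)
            positions.append(int(re.match(r"c\.(\d+)", cdna).group(1)))
        if not variants:
            raise ValueError(f"patient {row['patient_id']}: no variants")
        if len(variants) > 3:
            raise ValueError(f"patient {row['patient_id']}: more than 3 variants")
        phase = str(row.get("phase", "")).strip()
        if len(variants) == 1:
            groups = [[variants[0]]]
        elif phase:
            labels = phase.split("|")
            if len(labels) != len(variants) or not set(labels) <= {"1", "2"}:
                raise ValueError(
                    f"patient {row['patient_id']}: phase {phase!r} inconsistent "
                    f"with {len(variants)} variants"
                )
            groups = [
                [v for v, l in zip(variants, labels) if l == g]
                for g in ("1", "2")
            ]
            groups = [g for g in groups if g]
            if len(variants) >= 2 and len(groups) != 2:
                raise ValueError(
                    f"patient {row['patient_id']}: phase {phase!r} puts all "
                    "variants on one allele"
                )
        elif len(variants) == 2:
            groups = [[variants[0]], [variants[1]]]
        else:  # 3 variants, no phase: two most-5' cis, by documented default
            order = sorted(range(3), key=lambda i: positions[i])
            warnings.warn(
                f"patient {row['patient_id']}: no phase for 3 variants; "
                "defaulting to the two most-5' variants in cis"
            )
            groups = [[variants[order[0]], variants[order[1]]], [variants[order[2]]]]
        patients.append(PatientRecord(str(row["patient_id"]), str(row["phenotype"]), groups))
    return patients


def load_table1() -> list[PatientRecord]:
    """The packaged transcription of the published 51-proband cohort table."""
    with resources.files("poremut.data").joinpath("table1_cohort.tsv").open("r") as fh:
        return load_cohort(fh)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def allele_frequencies(cohort: list[PatientRecord]) -> CohortSummary:
    """Per-mutation disease-allele counts and percentages."""
    if not cohort:
        raise ValueError("empty cohort")
    n_alleles = sum(len(p.alleles) for p in cohort)
    counts: dict[str, int] = {}
    protein_labels: dict[str, str] = {}
    for p in cohort:
        for group in p.alleles:
            for v in group:
                counts[v.cdna] = counts.get(v.cdna, 0) + 1
                if v.protein:
                    protein_labels[v.cdna] = v.protein
    percentages = {
        cdna: round_half_away(100.0 * c / n_alleles, 1) for cdna, c in counts.items()
    }
    return CohortSummary(
        n_patients=len(cohort),
        n_disease_alleles=n_alleles,
        allele_counts=counts,
        percentages=percentages,
        protein_labels=protein_labels,
        n_distinct_mutations=len(counts),
        novel=summarize_novel(cohort),
    )


_TRUNCATING = {"frameshift", "splice", "nonsense", "large_del"}


def summarize_novel(cohort: list[PatientRecord]) -> dict[str, int]:
    """Distinct novel mutation types, split truncating/splice vs missense."""
    novel_types: dict[str, str] = {}
    for p in cohort:
        for v in p.variants():
            if v.novel:
                novel_types[v.cdna] = v.variant_class
    trunc = sum(1 for c in novel_types.values() if c in _TRUNCATING)
    missense = sum(1 for c in novel_types.values() if c == "missense")
    return {
        "total_novel_types": len(novel_types),
        "novel_truncating_or_splice": trunc,
        "novel_missense": missense,
    }


def summary_frame(summary: CohortSummary) -> pd.DataFrame:
    """Tidy per-mutation table sorted by descending allele count."""
    rows = [
        {
            "cdna": cdna,
            "protein": summary.protein_labels.get(cdna, ""),
            "alleles": count,
            "percent": summary.percentages[cdna],
        }
        for cdna, count in summary.allele_counts.items()
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["alleles", "cdna"], ascending=[False, True])
        .reset_index(drop=True)
    )
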