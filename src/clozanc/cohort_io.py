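"""Cohort input handling: file parsing, genotype hard-calling, variant QC,
phenotype definition from absolute neutrophil counts, and ancestry grouping.

The pipeline consumes three plain-text files:

* a single-site VCF 4.2 carrying ``GT`` and optionally ``GP`` (genotype
  posterior probabilities in 0/0, 0/1, 1/1 order) for the focal variant;
* a tab-separated phenotype/covariate table with columns
  ``subject_id  anc  clinical_case  sex  age  pc1..pc7  frac_afr  frac_eas
  frac_eur  site`` (missing values written as ``NA``);
* a tab-separated local-ancestry dosage table with columns
  ``subject_id  marker_id  pos  dos_afr  dos_eas  dos_eur``.

Hard calls follow the max-posterior ("best guess") rule: the argmax genotype
is kept when its posterior probability is at least the call threshold
(default 0.7, equality keeps the call), otherwise the call is set missing.
Phenotype classes are derived from the absolute neutrophil count (ANC, in
cells/mm^3): ANC <= 500 is agranulocytosis, 500 < ANC <= 1500 neutropenia,
ANC > 1500 control, with both boundaries inclusive.  Subjects without an ANC
are classifiable only when flagged as clinical-judgement cases.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy.special import gammaln

logger = logging.getLogger("clozanc")

POPULATIONS = ("AFR", "EAS", "EUR")
FRACTION_COLUMNS = ("frac_afr", "frac_eas", "frac_eur")
PC_COLUMNS = tuple(f"pc{i}" for i in range(1, 8))
PHENOTYPE_COLUMNS = (
    ("subject_id", "anc", "clinical_case", "sex", "age")
    + PC_COLUMNS
    + FRACTION_COLUMNS
    + ("site",)
)
LOCAL_ANCESTRY_COLUMNS = (
    "subject_id",
    "marker_id",
    "pos",
    "dos_afr",
    "dos_eas",
    "dos_eur",
)

NEUTROPENIA_THRESHOLD = 1500.0
AGRANULOCYTOSIS_THRESHOLD = 500.0
CALL_THRESHOLD = 0.7
ANCESTRY_FRACTION_THRESHOLD = 0.8


class CohortValidationError(ValueError):
    """Malformed or inconsistent cohort input."""


class UnclassifiableSubjectError(CohortValidationError):
    """Subject has no ANC and no clinical-judgement flag."""


class NoCasesError(RuntimeError):
    """An analysis stage received a cohort without cases (or controls)."""


class PhenotypeClass(enum.Enum):
    CONTROL = "control"
    NEUTROPENIA_ONLY = "neutropenia_only"
    AGRANULOCYTOSIS = "agranulocytosis"

    @property
    def is_neutropenia(self) -> bool:
        """Neutropenia is the union class: agranulocytosis cases count."""
        return self is not PhenotypeClass.CONTROL


class AncestryGroup(enum.Enum):
    EUR = "EUR"
    AFR = "AFR"
    ADMIXED = "admixed"


# ---------------------------------------------------------------------------
# genotype hard-calling


def _validated_gp(gp: np.ndarray) -> np.ndarray:
    gp = np.asarray(gp, dtype=float)
    if gp.ndim == 1:
        gp = gp[None, :]
    if gp.shape[1] != 3:
        raise CohortValidationError(
            f"genotype probabilities must have 3 entries, got shape {gp.shape}"
        )
    if not np.all(np.isfinite(gp)) or np.any(gp < -1e-12):
        raise CohortValidationError("genotype probabilities must be finite and nonnegative")
    sums = gp.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-4):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise CohortValidationError(
            f"genotype probabilities must sum to 1 within 1e-4 (row {bad}: sum={sums[bad]:.6f})"
        )
    return gp / sums[:, None]


def hard_calls_from_gp(gp: np.ndarray, threshold: float = CALL_THRESHOLD) -> np.ndarray:
    """Vectorised best-guess calls from an (n, 3) posterior array.

    Returns a float array with values in {0, 1, 2} and NaN for missing
    (max posterior below ``threshold``, or an exact tie at the maximum).
    """
    gp = _validated_gp(gp)
    order = np.sort(gp, axis=1)
    top, second = order[:, 2], order[:, 1]
    calls = np.argmax(gp, axis=1).astype(float)
    calls[(top < threshold) | (top - second <= 1e-12)] = np.nan
    return calls


def best_guess(gp: Sequence[float], threshold: float = CALL_THRESHOLD) -> Optional[int]:
    """Best-guess genotype for one subject: argmax of the 3-simplex posterior.

    The call is kept when ``max(gp) >= threshold`` (equality kept, because
    only calls *below* the threshold are set missing); exact ties at the
    maximum are returned as missing (``None``).
    """
    call = hard_calls_from_gp(np.asarray(gp, dtype=float)[None, :], threshold)[0]
    return None if np.isnan(call) else int(call)


# ---------------------------------------------------------------------------
# phenotype and ancestry classification


def define_phenotype(
    anc: Optional[float],
    clinical_flag: bool = False,
    *,
    clinical_class: PhenotypeClass = PhenotypeClass.NEUTROPENIA_ONLY,
    neut_threshold: float = NEUTROPENIA_THRESHOLD,
    agran_threshold: float = AGRANULOCYTOSIS_THRESHOLD,
) -> PhenotypeClass:
    """Phenotype class from the absolute neutrophil count.

    ANC <= ``agran_threshold`` is agranulocytosis, up to ``neut_threshold``
    neutropenia, above it control (boundaries inclusive).  A missing ANC is
    classifiable only for clinical-judgement cases, which take
    ``clinical_class`` (per-record annotation decides neutropenia vs
    agranulocytosis).
    """
    if not (0 < agran_threshold < neut_threshold):
        raise CohortValidationError(
            f"need 0 < agran_threshold < neut_threshold, got {agran_threshold}, {neut_threshold}"
        )
    if anc is None or (isinstance(anc, float) and math.isnan(anc)):
        if clinical_flag:
            return clinical_class
        raise UnclassifiableSubjectError("missing ANC without clinical-judgement flag")
    if anc < 0:
        raise CohortValidationError(f"ANC must be nonnegative, got {anc}")
    if anc <= agran_threshold:
        return PhenotypeClass.AGRANULOCYTOSIS
    if anc <= neut_threshold:
        return PhenotypeClass.NEUTROPENIA_ONLY
    return PhenotypeClass.CONTROL


def classify_phenotypes(
    phenotypes: pd.DataFrame,
    *,
    neut_threshold: float = NEUTROPENIA_THRESHOLD,
    agran_threshold: float = AGRANULOCYTOSIS_THRESHOLD,
) -> tuple[pd.Series, list[str]]:
    """Classify every subject of a phenotype table.

    Returns ``(classes, unclassifiable_ids)`` where ``classes`` is indexed by
    subject_id and unclassifiable subjects (missing ANC, no clinical flag)
    are reported rather than silently dropped.
    """
    classes: dict[str, PhenotypeClass] = {}
    unclassifiable: list[str] = []
    for sid, row in phenotypes.iterrows():
        flag, cclass = _parse_clinical(row.get("clinical_case"))
        try:
            classes[sid] = define_phenotype(
                row["anc"],
                flag,
                clinical_class=cclass,
                neut_threshold=neut_threshold,
                agran_threshold=agran_threshold,
            )
        except UnclassifiableSubjectError:
            unclassifiable.append(sid)
    if unclassifiable:
        logger.warning(
            "%d subject(s) unclassifiable (missing ANC without clinical flag): %s",
            len(unclassifiable),
            ", ".join(unclassifiable[:10]) + ("..." if len(unclassifiable) > 10 else ""),
        )
    return pd.Series(classes, name="phenotype_class"), unclassifiable


def _parse_clinical(value) -> tuple[bool, PhenotypeClass]:
    """Parse the clinical_case column: 0 / 1 / 'agran'."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False, PhenotypeClass.NEUTROPENIA_ONLY
    text = str(value).strip().lower()
    if text in ("", "0", "0.0", "na"):
        return False, PhenotypeClass.NEUTROPENIA_ONLY
    if text in ("1", "1.0"):
        return True, PhenotypeClass.NEUTROPENIA_ONLY
    if text == "agran":
        return True, PhenotypeClass.AGRANULOCYTOSIS
    raise CohortValidationError(f"clinical_case must be one of 0, 1, agran; got {value!r}")


def classify_ancestry_group(
    global_fractions: Sequence[float],
    threshold: float = ANCESTRY_FRACTION_THRESHOLD,
    populations: Sequence[str] = POPULATIONS,
) -> AncestryGroup:
    """Ancestry stratum from global ancestry fractions.

    EUR (resp. AFR) when the corresponding fraction is at least ``threshold``
    (default 80%); everyone else is admixed.
    """
    frac = np.asarray(global_fractions, dtype=float)
    if frac.shape != (len(populations),) or np.any(frac < -1e-9):
        raise CohortValidationError(f"invalid ancestry fractions {global_fractions!r}")
    if abs(frac.sum() - 1.0) > 1e-6:
        raise CohortValidationError(
            f"ancestry fractions must sum to 1 within 1e-6, got {frac.sum():.8f}"
        )
    lookup = dict(zip(populations, frac))
    if lookup["EUR"] >= threshold:
        return AncestryGroup.EUR
    if lookup["AFR"] >= threshold:
        return AncestryGroup.AFR
    return AncestryGroup.ADMIXED


def classify_ancestry_groups(
    phenotypes: pd.DataFrame, threshold: float = ANCESTRY_FRACTION_THRESHOLD
) -> pd.Series:
    """Vectorised ancestry grouping over the phenotype table."""
    frac = phenotypes.loc[:, list(FRACTION_COLUMNS)].to_numpy(dtype=float)
    sums = frac.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        bad = phenotypes.index[np.argmax(np.abs(sums - 1.0))]
        raise CohortValidationError(
            f"global ancestry fractions of subject {bad} do not sum to 1"
        )
    groups = np.full(len(frac), AncestryGroup.ADMIXED, dtype=object)
    groups[frac[:, 2] >= threshold] = AncestryGroup.EUR
    groups[frac[:, 0] >= threshold] = AncestryGroup.AFR
    return pd.Series(groups, index=phenotypes.index, name="ancestry_group")


# ---------------------------------------------------------------------------
# variant QC


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided Hardy-Weinberg exact test on genotype counts.

    The p-value is the total probability, under the conditional distribution
    of the heterozygote count given allele counts, of all configurations no
    more probable than the observed one (standard exact test, no mid-p).
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 or int(c) != c for c in counts):
        raise CohortValidationError(f"genotype counts must be nonnegative integers: {counts}")
    n = sum(counts)
    if n == 0:
        raise CohortValidationError("no genotypes for HWE test")
    n_ref = 2 * n_hom_ref + n_het
    n_alt = 2 * n_hom_alt + n_het
    rare = min(n_ref, n_alt)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    logw = (
        math.lgamma(n + 1)
        - gammaln(hom_rare + 1.0)
        - gammaln(hets + 1.0)
        - gammaln(hom_common + 1.0)
        + hets * math.log(2.0)
    )
    w = np.exp(logw - logw.max())
    probs = w / w.sum()
    obs = int(np.flatnonzero(hets == n_het)[0])
    return float(min(1.0, probs[probs <= probs[obs] * (1 + 1e-9)].sum()))


@dataclass
class VariantQCReport:
    """Single-variant QC: missingness, minor-allele frequency, HWE."""

    variant_id: str
    call_rate: float
    maf: float
    hwe_p: float
    pass_qc: bool
    n: int
    n_missing: int
    failures: list[str] = field(default_factory=list)


def variant_qc(
    hard_calls: np.ndarray,
    *,
    variant_id: str = "",
    geno: float = 0.1,
    maf: float = 0.01,
    hwe: float = 1e-5,
    hwe_mask: Optional[np.ndarray] = None,
) -> VariantQCReport:
    """Apply the missingness / MAF / HWE filters to one variant.

    ``geno`` is the maximum missing-call fraction, ``maf`` the minimum minor
    allele frequency and ``hwe`` the minimum exact-test p-value.  The HWE
    test is evaluated on the subset selected by ``hwe_mask`` (typically
    controls) when given, otherwise on all non-missing calls.
    """
    calls = np.asarray(hard_calls, dtype=float)
    missing = np.isnan(calls)
    n = calls.size
    if n == 0 or missing.all():
        raise CohortValidationError("variant QC requires at least one non-missing call")
    observed = calls[~missing]
    miss_frac = missing.mean()
    freq = observed.sum() / (2.0 * observed.size)
    maf_value = min(freq, 1.0 - freq)
    hwe_calls = calls[np.asarray(hwe_mask, bool) & ~missing] if hwe_mask is not None else observed
    if hwe_calls.size == 0:
        hwe_calls = observed
    counts = np.bincount(hwe_calls.astype(int), minlength=3)
    hwe_p = hwe_exact_test(int(counts[0]), int(counts[1]), int(counts[2]))
    failures = []
    if miss_frac > geno:
        failures.append(f"geno ({miss_frac:.4f} > {geno})")
    if maf_value < maf:
        failures.append(f"maf ({maf_value:.4f} < {maf})")
    if hwe_p < hwe:
        failures.append(f"hwe ({hwe_p:.3e} < {hwe})")
    return VariantQCReport(
        variant_id=variant_id,
        call_rate=float(1.0 - miss_frac),
        maf=float(maf_value),
        hwe_p=hwe_p,
        pass_qc=not failures,
        n=n,
        n_missing=int(missing.sum()),
        failures=failures,
    )


def genotype_class_count(hard_calls: np.ndarray, genotype_class: int) -> int:
    """Number of non-missing calls equal to ``genotype_class`` (0, 1 or 2)."""
    calls = np.asarray(hard_calls, dtype=float)
    return int(np.nansum(calls == genotype_class))


def carrier_table(
    hard_calls: pd.Series,
    phenotypes: pd.Series,
    ancestry_groups: pd.Series,
) -> pd.DataFrame:
    """Cross-tabulate risk-allele carriers by ancestry group and phenotype.

    Carriers hold at least one risk allele (hard call >= 1).  The returned
    frame has one row per (ancestry group, phenotype class) plus per-group
    and overall totals, with carrier / non-carrier / missing counts and the
    risk-allele frequency of the stratum.
    """
    for other in (phenotypes, ancestry_groups):
        if set(other.index) != set(hard_calls.index):
            raise CohortValidationError("carrier_table inputs must share subject ids")
    df = pd.DataFrame(
        {
            "call": hard_calls,
            "phenotype": phenotypes.reindex(hard_calls.index).map(lambda c: c.value),
            "group": ancestry_groups.reindex(hard_calls.index).map(lambda g: g.value),
        }
    )
    rows = []

    def _summarise(sub: pd.DataFrame, group: str, phenotype: str) -> None:
        calls = sub["call"].to_numpy(dtype=float)
        missing = np.isnan(calls)
        observed = calls[~missing]
        freq = observed.sum() / (2.0 * observed.size) if observed.size else 0.0
        rows.append(
            {
                "ancestry_group": group,
                "phenotype": phenotype,
                "n": len(sub),
                "carriers": int((observed >= 1).sum()),
                "non_carriers": int((observed == 0).sum()),
                "missing": int(missing.sum()),
                "risk_allele_freq": float(freq),
            }
        )

    for group, by_group in df.groupby("group", sort=True):
        for phenotype, sub in by_group.groupby("phenotype", sort=True):
            _summarise(sub, group, phenotype)
        _summarise(by_group, group, "all")
    _summarise(df, "all", "all")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file readers


@dataclass
class Cohort:
    """The three aligned inputs of one analysis run."""

    phenotypes: pd.DataFrame  # indexed by subject_id
    genotypes: pd.DataFrame  # subject_id, variant_id, gp0..gp2, hard_call
    local_ancestry: pd.DataFrame  # long: subject_id, marker_id, pos, dosages

    @property
    def subject_ids(self) -> pd.Index:
        return self.phenotypes.index


def read_phenotypes(path: Path | str) -> pd.DataFrame:
    """Read the phenotype/covariate TSV and validate the ancestry simplex."""
    df = pd.read_csv(
        path,
        sep="\t",
        na_values=["NA"],
        keep_default_na=False,
        dtype={"subject_id": str, "clinical_case": str, "site": str},
    )
    missing_cols = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortValidationError(f"phenotype table misses columns: {missing_cols}")
    if df["subject_id"].duplicated().any():
        raise CohortValidationError("duplicate subject ids in phenotype table")
    df = df.set_index("subject_id")
    frac = df.loc[:, list(FRACTION_COLUMNS)].to_numpy(dtype=float)
    if np.any(np.abs(frac.sum(axis=1) - 1.0) > 1e-6):
        raise CohortValidationError("global ancestry fractions must sum to 1 within 1e-6")
    for row in df.itertuples():
        _parse_clinical(row.clinical_case)  # fail fast on malformed flags
    return df


def read_local_ancestry(path: Path | str, *, sum_tol: float = 1e-3) -> pd.DataFrame:
    """Read the local-ancestry dosage TSV (ELAI-style long layout).

    Per marker the three population dosages must sum to 2 within ``sum_tol``
    (dosage estimates are noisy; the tolerance is configurable).
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"subject_id": str, "marker_id": str})
    missing_cols = [c for c in LOCAL_ANCESTRY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortValidationError(f"local-ancestry table misses columns: {missing_cols}")
    dos = df.loc[:, ["dos_afr", "dos_eas", "dos_eur"]].to_numpy(dtype=float)
    if np.any(dos < -1e-9) or np.any(dos > 2 + 1e-9):
        raise CohortValidationError("local-ancestry dosages must lie in [0, 2]")
    if np.any(np.abs(dos.sum(axis=1) - 2.0) > sum_tol):
        raise CohortValidationError(
            f"local-ancestry dosages must sum to 2 within {sum_tol} per marker"
        )
    return df


def read_vcf(
    path: Path | str,
    *,
    risk_is_alt: bool = True,
    call_threshold: float = CALL_THRESHOLD,
) -> pd.DataFrame:
    """Read the focal-variant VCF into a genotype frame.

    Hard calls are derived from ``GP`` with the max-posterior rule when GP is
    present, otherwise taken from ``GT``.  Counts (and GP order) are always
    reported for the risk allele, which is ALT by default.
    """
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                raise CohortValidationError("expected a biallelic focal variant")
            risk_allele = rec.alts[0] if risk_is_alt else rec.ref
            for sample in rec.samples.values():
                gp = sample.get("GP")
                gt = sample.get("GT")
                records.append(
                    {
                        "subject_id": sample.name,
                        "variant_id": rec.id or f"{rec.chrom}:{rec.pos}",
                        "pos": rec.pos,
                        "risk_allele": risk_allele,
                        "gp": None if gp is None else tuple(float(x) for x in gp),
                        "gt": gt,
                    }
                )
            break  # single-site file by contract
    if not records:
        raise CohortValidationError(f"no variant records in {path}")
    df = pd.DataFrame(records)
    if df["gp"].notna().all():
        gp = np.array(df["gp"].tolist(), dtype=float)
        if not risk_is_alt:
            gp = gp[:, ::-1]
        calls = hard_calls_from_gp(gp, call_threshold)
    else:
        gp = np.full((len(df), 3), np.nan)
        calls = np.array(
            [
                np.nan
                if gt is None or any(a is None for a in gt)
                else float(sum(1 for a in gt if a == (1 if risk_is_alt else 0)))
                for gt in df["gt"]
            ]
        )
    out = df.loc[:, ["subject_id", "variant_id", "pos", "risk_allele"]].copy()
    out[["gp0", "gp1", "gp2"]] = gp
    out["hard_call"] = calls
    return out


def read_cohort(
    vcf_path: Path | str,
    phenotype_path: Path | str,
    local_ancestry_path: Path | str,
    *,
    risk_is_alt: bool = True,
    call_threshold: float = CALL_THRESHOLD,
) -> Cohort:
    """Read and cross-validate the three cohort files."""
    phenotypes = read_phenotypes(phenotype_path)
    genotypes = read_vcf(vcf_path, risk_is_alt=risk_is_alt, call_threshold=call_threshold)
    local_ancestry = read_local_ancestry(local_ancestry_path)
    pheno_ids = set(phenotypes.index)
    for name, ids in (
        ("VCF", set(genotypes["subject_id"])),
        ("local-ancestry table", set(local_ancestry["subject_id"])),
    ):
        if ids != pheno_ids:
            extra = sorted(ids ^ pheno_ids)[:5]
            raise CohortValidationError(
                f"subject ids of {name} do not match the phenotype table (e.g. {extra})"
            )
    return Cohort(phenotypes=phenotypes, genotypes=genotypes, local_ancestry=local_ancestry)
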