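"""Synthetic admixed cohorts with an ancestry-linked pharmacogenetic risk allele.

The generator produces, at desk scale, cohorts with the statistical
structure the analysis pipeline assumes:

* per-subject global ancestry proportions on the AFR/EAS/EUR simplex, drawn
  from a Dirichlet concentrated on European ancestry;
* two haplotypes per subject, each a tiling of the region by ancestry
  tracts whose switch points follow a homogeneous (memoryless) Poisson
  process and whose labels are drawn from the subject's global proportions
  -- a continuous stand-in for "mixture generations x recombination";
* a risk allele at the focal position carried by each haplotype with an
  ancestry-dependent probability, so that carriers sit preferentially on an
  East-Asian-like local background;
* case status from a liability (logistic) model combining the risk-allele
  count with, in non-carriers, the local AFR-vs-EAS normed dosage contrast;
* absolute neutrophil counts placing controls above 1500 cells/mm^3 and
  splitting cases between agranulocytosis (<= 500) and the neutropenia band,
  with optional clinical-judgement cases (flagged, ANC missing) and
  register-style missing control ANC.

All randomness flows through one NumPy generator keyed by the seed, with a
fixed draw order (global proportions, switch counts, switch positions,
tract labels, haplotype risk alleles, genotype-probability noise, case
draws, ANC draws, clinical/missing flags, covariates), so emitted cohorts
are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort_io import CohortValidationError, POPULATIONS

FOCAL_VARIANT_ID = "rs_focal"
RISK_ALLELE = "G"
NON_RISK_ALLELE = "A"


@dataclass(frozen=True)
class AncParams:
    """Absolute-neutrophil-count model of the generator.

    Controls are drawn from a normal reflected above ``control_floor`` so
    that every recorded control ANC exceeds the neutropenia threshold.
    Cases are a two-component mixture: a fraction ``agran_frac`` falls in
    the agranulocytosis range, the remainder in the neutropenia band
    (uniform draws within each range).  ``genotype_anc_gradient`` > 0
    replaces the mixture with genotype-tilted Beta draws over (0, 1500]
    (carrier cases skewed low, non-carrier cases skewed high), planting a
    monotone ANC-risk relationship for threshold-sweep studies.
    """

    control_mean: float = 4200.0
    control_sd: float = 1100.0
    control_floor: float = 1550.0
    agran_frac: float = 0.34
    agran_range: tuple[float, float] = (50.0, 500.0)
    neut_range: tuple[float, float] = (500.0, 1500.0)
    genotype_anc_gradient: float = 0.0
    control_missing_prob: float = 0.02
    clinical_case_frac: float = 0.12
    clinical_agran_frac: float = 3.0 / 22.0


@dataclass(frozen=True)
class SimParams:
    """Generator settings; defaults emulate a European-dominant admixed cohort.

    ``switch_rate`` is the expected number of ancestry switches per megabase
    per haplotype; ``p_risk_by_ancestry`` gives, per population in
    ``populations`` order, the probability that a haplotype carries the risk
    allele at ``focal_pos`` (defaults: rare on AFR/EUR backgrounds, enriched
    on EAS).  ``beta0``/``beta_G``/``beta_LA`` parameterise the liability
    model: baseline log-odds, log-OR per risk allele, and log-OR per unit of
    the AFR-vs-EAS normed dosage contrast in non-carriers.
    """

    n_subjects: int = 1000
    region_start: int = 25_000_000
    region_end: int = 35_000_000
    n_markers: int = 25
    focal_pos: int = 32_660_000
    populations: tuple[str, ...] = POPULATIONS
    global_props_alpha: tuple[float, ...] = (1.5, 1.5, 27.0)
    fixed_global_props: Optional[tuple[float, ...]] = None
    switch_rate: float = 2.0  # switches / Mb / haplotype
    p_risk_by_ancestry: tuple[float, ...] = (0.01, 0.15, 0.01)
    beta0: float = -2.0
    beta_G: float = math.log(6.2)
    beta_LA: float = 1.5
    anc_params: AncParams = field(default_factory=AncParams)
    gp_noise: float = 0.0
    la_noise: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise CohortValidationError("n_subjects must be positive")
        if not self.region_start < self.region_end:
            raise CohortValidationError("region_start must be below region_end")
        if self.n_markers < 2:
            raise CohortValidationError("n_markers must be at least 2")
        if not self.region_start <= self.focal_pos <= self.region_end:
            raise CohortValidationError("focal_pos must lie inside the region")
        if self.switch_rate < 0:
            raise CohortValidationError("switch_rate must be nonnegative")
        K = len(self.populations)
        if len(self.p_risk_by_ancestry) != K or not all(
            0 <= p <= 1 for p in self.p_risk_by_ancestry
        ):
            raise CohortValidationError("p_risk_by_ancestry entries must lie in [0, 1]")
        if self.fixed_global_props is not None:
            props = np.asarray(self.fixed_global_props, dtype=float)
            if props.shape != (K,) or abs(props.sum() - 1.0) > 1e-9 or np.any(props < 0):
                raise CohortValidationError("fixed_global_props must lie on the K-simplex")
        elif len(self.global_props_alpha) != K or any(a <= 0 for a in self.global_props_alpha):
            raise CohortValidationError("global_props_alpha must be positive, length K")
        if not 0 <= self.gp_noise < 1 or not 0 <= self.la_noise < 1:
            raise CohortValidationError("noise levels must lie in [0, 1)")


# ---------------------------------------------------------------------------
# ancestry tracts


@dataclass
class HaplotypeTractSet:
    """Tract decomposition of two haplotypes per subject, in flat arrays.

    ``breaks`` holds all interior switch positions concatenated over
    haplotypes (haplotypes 2i and 2i+1 belong to subject i), ``offsets``
    indexes haplotype slices into it, and ``labels`` (offset by
    ``label_offsets``) stores one population index per tract
    (n_breaks + 1 tracts per haplotype).
    """

    region_start: float
    region_end: float
    populations: tuple[str, ...]
    breaks: np.ndarray
    offsets: np.ndarray
    labels: np.ndarray
    label_offsets: np.ndarray
    global_props: np.ndarray  # (n_subjects, K)

    @property
    def n_haplotypes(self) -> int:
        return len(self.offsets) - 1

    @property
    def n_subjects(self) -> int:
        return self.n_haplotypes // 2

    def n_switches(self) -> np.ndarray:
        """Interior switch count per haplotype."""
        return np.diff(self.offsets)

    def tracts(self, subject: int) -> list[list[tuple[float, float, str]]]:
        """Tract lists [(start, end, population), ...] for both haplotypes."""
        out = []
        for hap in (2 * subject, 2 * subject + 1):
            edges = np.concatenate(
                [[self.region_start], self.breaks[self.offsets[hap] : self.offsets[hap + 1]], [self.region_end]]
            )
            labels = self.labels[self.label_offsets[hap] : self.label_offsets[hap + 1]]
            out.append(
                [
                    (float(edges[i]), float(edges[i + 1]), self.populations[labels[i]])
                    for i in range(len(labels))
                ]
            )
        return out

    def tract_lengths(self, interior_only: bool = False) -> np.ndarray:
        """All tract lengths; optionally only tracts bounded by two switches."""
        lengths = []
        for hap in range(self.n_haplotypes):
            edges = np.concatenate(
                [[self.region_start], self.breaks[self.offsets[hap] : self.offsets[hap + 1]], [self.region_end]]
            )
            seg = np.diff(edges)
            if interior_only:
                seg = seg[1:-1]
            lengths.append(seg)
        return np.concatenate(lengths) if lengths else np.empty(0)

    def populations_at(self, pos: float) -> np.ndarray:
        """Population index of the tract containing ``pos``, per haplotype."""
        if not self.region_start <= pos <= self.region_end:
            raise CohortValidationError(f"position {pos} outside the simulated region")
        below = np.concatenate([[0], np.cumsum(self.breaks <= pos)])
        tract_idx = below[self.offsets[1:]] - below[self.offsets[:-1]]
        return self.labels[self.label_offsets[:-1] + tract_idx]

    def dosages_at(self, positions: Sequence[float]) -> np.ndarray:
        """Integer ancestry dosages, shape (n_subjects, n_positions, K).

        At every position the K dosages are each in {0, 1, 2} and sum to 2
        (one contribution per haplotype).
        """
        K = len(self.populations)
        out = np.zeros((self.n_subjects, len(positions), K), dtype=np.int64)
        for j, pos in enumerate(positions):
            pops = self.populations_at(pos)
            np.add.at(out[:, j, :], (np.arange(self.n_subjects), pops[0::2]), 1)
            np.add.at(out[:, j, :], (np.arange(self.n_subjects), pops[1::2]), 1)
        return out


def subject_ids(n: int) -> pd.Index:
    return pd.Index([f"S{i + 1:05d}" for i in range(n)], name="subject_id")


def simulate_tracts(params: SimParams, rng: Optional[np.random.Generator] = None) -> HaplotypeTractSet:
    """Draw ancestry tracts for every haplotype.

    Switch points form a homogeneous Poisson process with intensity
    ``switch_rate`` per megabase; tract labels are independent draws from
    the subject's global ancestry proportions, making the tract process
    memoryless (self-transitions are retained as distinct tracts).
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n, K = params.n_subjects, len(params.populations)
    n_haps = 2 * n
    if params.fixed_global_props is not None:
        props = np.tile(np.asarray(params.fixed_global_props, dtype=float), (n, 1))
    else:
        props = rng.dirichlet(params.global_props_alpha, size=n)
    length_mb = (params.region_end - params.region_start) / 1e6
    n_switch = rng.poisson(params.switch_rate * length_mb, size=n_haps)
    total = int(n_switch.sum())
    raw = params.region_start + rng.random(total) * (params.region_end - params.region_start)
    hap_of_break = np.repeat(np.arange(n_haps), n_switch)
    order = np.lexsort((raw, hap_of_break))
    breaks = raw[order]
    offsets = np.concatenate([[0], np.cumsum(n_switch)])
    n_tracts = n_switch + 1
    label_offsets = np.concatenate([[0], np.cumsum(n_tracts)])
    hap_of_tract = np.repeat(np.arange(n_haps), n_tracts)
    with np.errstate(divide="ignore"):
        logp = np.log(props[hap_of_tract // 2])
    gumbel = rng.gumbel(size=(len(hap_of_tract), K))
    labels = np.argmax(logp + gumbel, axis=1)
    return HaplotypeTractSet(
        region_start=float(params.region_start),
        region_end=float(params.region_end),
        populations=params.populations,
        breaks=breaks,
        offsets=offsets,
        labels=labels,
        label_offsets=label_offsets,
        global_props=props,
    )


# ---------------------------------------------------------------------------
# genotypes, phenotypes, local ancestry


def assign_focal_genotypes(
    tracts: HaplotypeTractSet,
    params: SimParams,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Risk-allele genotypes at the focal position, coupled to local ancestry.

    Each haplotype carries the risk allele with the probability attached to
    its ancestral population at ``focal_pos``; the genotype is the sum over
    the two haplotypes.  Genotype posteriors are a point mass on the true
    genotype unless ``gp_noise`` blends in a symmetric Dirichlet draw.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    pops = tracts.populations_at(params.focal_pos)
    p_risk = np.asarray(params.p_risk_by_ancestry, dtype=float)[pops]
    carries = rng.random(tracts.n_haplotypes) < p_risk
    genotype = (carries[0::2].astype(int) + carries[1::2].astype(int))
    gp = np.zeros((tracts.n_subjects, 3))
    gp[np.arange(tracts.n_subjects), genotype] = 1.0
    if params.gp_noise > 0:
        noise = rng.dirichlet((1.0, 1.0, 1.0), size=tracts.n_subjects)
        gp = (1.0 - params.gp_noise) * gp + params.gp_noise * noise
    df = pd.DataFrame(
        {
            "variant_id": FOCAL_VARIANT_ID,
            "pos": params.focal_pos,
            "risk_allele": RISK_ALLELE,
            "gp0": gp[:, 0],
            "gp1": gp[:, 1],
            "gp2": gp[:, 2],
            "true_genotype": genotype,
        },
        index=subject_ids(tracts.n_subjects),
    )
    return df


def _focal_normed_contrast(tracts: HaplotypeTractSet, focal_pos: float) -> np.ndarray:
    """AFR-vs-EAS normed dosage contrast at the focal position.

    Defined as 0 where neither AFR nor EAS haplotypes are present (the
    liability model then carries no local-ancestry signal for that subject).
    """
    dos = tracts.dosages_at([focal_pos])[:, 0, :].astype(float)
    afr, eas = dos[:, 0], dos[:, 1]
    total = afr + eas
    with np.errstate(invalid="ignore", divide="ignore"):
        nd = np.where(total > 0, (afr - eas) / np.where(total > 0, total, 1.0), 0.0)
    return nd


def simulate_phenotype_and_anc(
    genotypes: pd.DataFrame,
    tracts: HaplotypeTractSet,
    params: SimParams,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Case status, ANC values and covariates from the liability model.

    Case probability is ``expit(beta0 + beta_G G + beta_LA nd 1[G = 0])``
    with ``nd`` the focal AFR-vs-EAS normed contrast.  Returns
    ``(phenotypes, truth)``: the phenotype/covariate table in its file
    schema, and the ground-truth frame (case indicator, genotype, contrast).
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    ap = params.anc_params
    n = tracts.n_subjects
    ids = subject_ids(n)
    G = genotypes["true_genotype"].to_numpy()
    nd = _focal_normed_contrast(tracts, params.focal_pos)
    eta = params.beta0 + params.beta_G * G + params.beta_LA * nd * (G == 0)
    case = rng.random(n) < expit(eta)

    # ANC draws: all streams drawn for every subject to keep the draw order
    # independent of the realised case pattern.
    control_anc = ap.control_floor + np.abs(rng.normal(ap.control_mean, ap.control_sd, n) - ap.control_floor)
    u_mix = rng.random(n)
    u_agran = rng.uniform(ap.agran_range[0], ap.agran_range[1], n)
    u_neut = rng.uniform(ap.neut_range[0] + 1e-9, ap.neut_range[1], n)
    g = ap.genotype_anc_gradient
    u_beta = rng.beta(1.0 + g * (G == 0), 1.0 + g * (G > 0), n)
    if g > 0:
        case_anc = np.clip(1500.0 * u_beta, 10.0, 1500.0)
    else:
        case_anc = np.where(u_mix < ap.agran_frac, u_agran, u_neut)
    anc = np.where(case, case_anc, control_anc)

    clinical_draw = rng.random(n)
    clinical_kind = rng.random(n)
    control_missing = rng.random(n) < ap.control_missing_prob
    is_clinical = case & (clinical_draw < ap.clinical_case_frac)
    clinical_flag = np.where(
        is_clinical, np.where(clinical_kind < ap.clinical_agran_frac, "agran", "1"), "0"
    )
    anc = anc.copy()
    anc[is_clinical] = np.nan  # clinical-judgement cases bypass ANC thresholding
    anc[~case & control_missing] = np.nan

    sex = rng.integers(1, 3, n)
    age = np.clip(rng.normal(41.0, 11.0, n), 18.0, 70.0).round(1)
    pcs = rng.normal(0.0, 0.01, (n, 7))

    phenotypes = pd.DataFrame(
        {
            "anc": np.round(anc, 1),
            "clinical_case": clinical_flag,
            "sex": sex,
            "age": age,
            **{f"pc{i + 1}": pcs[:, i] for i in range(7)},
            "frac_afr": tracts.global_props[:, 0],
            "frac_eas": tracts.global_props[:, 1],
            "frac_eur": tracts.global_props[:, 2],
            "site": "S1",
        },
        index=ids,
    )
    truth = pd.DataFrame(
        {"case": case, "genotype": G, "focal_nd": nd, "eta": eta, "clinical": is_clinical},
        index=ids,
    )
    return phenotypes, truth


def marker_grid(params: SimParams) -> pd.DataFrame:
    """Marker positions: an even grid plus a triplet straddling the focal site.

    The focal marker and two flanks 800 bp away guarantee that the default
    1 kb analysis window always contains markers.
    """
    grid = np.linspace(params.region_start, params.region_end, params.n_markers).astype(np.int64)
    extra = np.array([params.focal_pos - 800, params.focal_pos, params.focal_pos + 800], dtype=np.int64)
    pos = np.unique(np.concatenate([grid, extra]))
    ids = [FOCAL_VARIANT_ID if p == params.focal_pos else f"M{i + 1:04d}" for i, p in enumerate(pos)]
    return pd.DataFrame({"marker_id": ids, "pos": pos})


def local_ancestry_table(
    tracts: HaplotypeTractSet, params: SimParams
) -> pd.DataFrame:
    """ELAI-style long dosage table over the marker grid.

    ``la_noise`` shrinks the integer tract dosages toward twice the global
    proportions, emulating the soft estimates of a local-ancestry HMM while
    preserving the sum-to-2 constraint exactly.
    """
    markers = marker_grid(params)
    dos = tracts.dosages_at(markers["pos"].to_numpy()).astype(float)
    if params.la_noise > 0:
        target = 2.0 * tracts.global_props[:, None, :]
        dos = (1.0 - params.la_noise) * dos + params.la_noise * target
    n, m, _ = dos.shape
    ids = subject_ids(n)
    return pd.DataFrame(
        {
            "subject_id": np.repeat(ids.to_numpy(), m),
            "marker_id": np.tile(markers["marker_id"].to_numpy(), n),
            "pos": np.tile(markers["pos"].to_numpy(), n),
            "dos_afr": dos[:, :, 0].ravel(),
            "dos_eas": dos[:, :, 1].ravel(),
            "dos_eur": dos[:, :, 2].ravel(),
        }
    )


@dataclass
class SimulatedCohort:
    params: SimParams
    tracts: HaplotypeTractSet
    genotypes: pd.DataFrame
    phenotypes: pd.DataFrame
    local_ancestry: pd.DataFrame
    truth: pd.DataFrame


def simulate_cohort(params: SimParams) -> SimulatedCohort:
    """Run the full generator under one seeded RNG stream."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    tracts = simulate_tracts(params, rng)
    genotypes = assign_focal_genotypes(tracts, params, rng)
    phenotypes, truth = simulate_phenotype_and_anc(genotypes, tracts, params, rng)
    la = local_ancestry_table(tracts, params)
    return SimulatedCohort(
        params=params,
        tracts=tracts,
        genotypes=genotypes,
        phenotypes=phenotypes,
        local_ancestry=la,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# emission


def _vcf_line_for(genotypes: pd.DataFrame, params: SimParams) -> str:
    fields = [
        "6",
        str(params.focal_pos),
        FOCAL_VARIANT_ID,
        NON_RISK_ALLELE,
        RISK_ALLELE,
        ".",
        "PASS",
        ".",
        "GT:GP",
    ]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    for row in genotypes.itertuples():
        gp = f"{row.gp0:.6f},{row.gp1:.6f},{row.gp2:.6f}"
        fields.append(f"{gt_map[int(row.true_genotype)]}:{gp}")
    return "\t".join(fields)


def emit_cohort(cohort: SimulatedCohort, out_dir: Path | str) -> dict[str, Path]:
    """Write the three cohort files plus a JSON sidecar of true parameters.

    Files: ``cohort.vcf`` (single site, GT from the true genotype, GP the
    emitted posteriors), ``phenotypes.tsv``, ``local_ancestry.tsv`` and
    ``sim_params.json``.  Output is deterministic for a fixed seed
    (fixed-precision floats, no timestamps).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "phenotypes": out / "phenotypes.tsv",
        "local_ancestry": out / "local_ancestry.tsv",
        "params": out / "sim_params.json",
    }
    header = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=6,length=171115067>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype posterior probabilities (0/0, 0/1, 1/1)">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(cohort.genotypes.index),
    ]
    paths["vcf"].write_text("\n".join(header + [_vcf_line_for(cohort.genotypes, cohort.params)]) + "\n")

    pheno = cohort.phenotypes.reset_index().copy()
    # keep the written ancestry fractions on the simplex despite rounding
    pheno["frac_afr"] = pheno["frac_afr"].round(6)
    pheno["frac_eas"] = pheno["frac_eas"].round(6)
    pheno["frac_eur"] = (1.0 - pheno["frac_afr"] - pheno["frac_eas"]).round(6)
    pheno.to_csv(paths["phenotypes"], sep="\t", index=False, na_rep="NA", float_format="%.6f")
    cohort.local_ancestry.to_csv(
        paths["local_ancestry"], sep="\t", index=False, na_rep="NA", float_format="%.6f"
    )
    payload = dataclasses.asdict(cohort.params)
    payload["n_cases_true"] = int(cohort.truth["case"].sum())
    paths["params"].write_text(json.dumps(payload, indent=2, sort_keys=True, default=list) + "\n")
    return paths
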