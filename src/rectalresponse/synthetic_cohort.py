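"""Synthetic rectal-cancer cohort generator.

Emits clinical tables and MAF-style mutation files with the statistical
structure the analysis pipeline assumes: confounded CR/ICR assignment
through a covariate logit, group-differential gene mutation
probabilities, planted co-occurring gene pairs (shared latent Bernoulli
factors calibrated to a requested dependence odds ratio), per-sample
passenger mutation totals, sub-threshold decoy variants that the
filtering stage must remove, and an optional closed-loop mode that
regenerates the response label from a known logistic model so that the
full prediction pipeline can be checked against planted coefficients.

Cohort scale defaults mimic a mixed targeted-panel rectal-cancer cohort
of 364 patients (104 complete, 260 incomplete responders).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import beta as beta_dist

from .cohort_io import MutationMatrix, VariantRecord

__all__ = [
    "GeneSpec",
    "PlantedPair",
    "ResponseCoefficients",
    "SimulationParams",
    "SyntheticTruth",
    "simulate_cohort",
    "write_fixture_bundle",
    "preset",
    "solve_latent_q",
    "truth_matrix",
    "records_from_frame",
]

MAF_COLUMNS = ["Hugo_Symbol", "Chromosome", "Start_Position", "Reference_Allele",
               "Tumor_Seq_Allele2", "Variant_Classification",
               "Tumor_Sample_Barcode", "t_depth", "AF"]

_CLASS_CHOICES = ("Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del",
                  "Frame_Shift_Ins", "Splice_Site", "In_Frame_Del")
_CLASS_PROBS = (0.70, 0.10, 0.07, 0.05, 0.05, 0.03)
_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class GeneSpec:
    """A driver-panel gene: baseline mutation frequency and CR log-odds shift."""

    name: str
    base_freq: float
    log_or: float = 0.0  # positive = enriched in complete responders

    def group_freq(self, is_cr: bool) -> float:
        return float(expit(logit(self.base_freq) + (self.log_or if is_cr else 0.0)))


@dataclass(frozen=True)
class PlantedPair:
    """A co-occurring gene pair with a target dependence odds ratio (> 1)."""

    gene_a: str
    gene_b: str
    log_or: float

    def __post_init__(self) -> None:
        if self.log_or <= 0:
            raise ValueError("planted pairs must have positive dependence log-OR")


@dataclass(frozen=True)
class ResponseCoefficients:
    """Generative logistic model for closed-loop response regeneration.

    Scale mirrors a clinically plausible complete-response model:
    smaller tumors, stage, any network-gene mutation, and the
    co-occurring-pair count category drive the CR probability.
    """

    intercept: float = -0.7
    tumor_size: float = math.log(0.79)
    stage3: float = math.log(0.71)
    network_gene: float = math.log(2.57)
    cooccur_12: float = math.log(1.57)
    cooccur_3plus: float = math.log(8.47)
    network_genes: tuple[str, ...] = ()


def _default_gene_panel() -> tuple[GeneSpec, ...]:
    # common colorectal drivers (higher in incomplete responders) plus
    # DNA-repair genes enriched in complete responders
    return (
        GeneSpec("TTN", 0.50, 0.10),
        GeneSpec("APC", 0.55, -0.35),
        GeneSpec("TP53", 0.60, -0.30),
        GeneSpec("KRAS", 0.40, -0.30),
        GeneSpec("PIK3CA", 0.20, -0.30),
        GeneSpec("FBXW7", 0.10, -0.30),
        GeneSpec("MSH3", 0.10, 0.60),
        GeneSpec("MLH1", 0.08, 0.60),
        GeneSpec("PMS1", 0.07, 0.60),
        GeneSpec("BRCA1", 0.09, 0.60),
        GeneSpec("BARD1", 0.07, 0.60),
        GeneSpec("POLD1", 0.08, 0.60),
        GeneSpec("POLE", 0.10, 0.60),
    )


@dataclass
class SimulationParams:
    """Everything needed to draw one synthetic cohort.

    The defaults are the package's reference study conditions: a
    364-patient cohort (104 CR / 260 ICR) with mildly confounded group
    assignment, targeted-panel mutation totals (~1.5 Mb coding
    footprint), DNA-repair genes enriched in complete responders, and
    two planted co-occurring repair-gene pairs.
    """

    n_cr: int = 104
    n_icr: int = 260
    # covariate distributions
    age_mean: float = 60.0
    age_sd: float = 10.0
    bmi_mean: float = 27.0
    bmi_sd: float = 5.0
    p_female: float = 0.35
    tumor_size_median: float = 4.6  # cm; confounded assignment shifts group medians
    tumor_size_sigma: float = 0.32  # log-scale sd
    p_stage3: float = 0.60
    # CR-assignment confounding: logit weights on standardized covariates
    # (keys: age, bmi, gender_female, tumor_size, stage3, age_sq, bmi_sq, size_sq)
    assignment_coefficients: dict[str, float] = field(default_factory=lambda: {
        "age": 0.25, "bmi": 0.25, "gender_female": 0.30, "tumor_size": -0.45,
    })
    gene_panel: tuple[GeneSpec, ...] = field(default_factory=_default_gene_panel)
    planted_pairs: tuple[PlantedPair, ...] = (
        PlantedPair("MSH3", "POLE", math.log(8.0)),
        PlantedPair("BRCA1", "BARD1", math.log(8.0)),
    )
    # per-sample total mutation counts (panel + passengers), by group
    tmb_mean_cr: float = 13.0
    tmb_mean_icr: float = 9.0
    coding_length_mb: float = 1.5  # targeted-panel coding footprint
    n_passenger_genes: int = 300
    decoy_fraction: float = 0.2  # extra sub-threshold variants, fraction of retained
    depth_mean: float = 80.0
    # closed-loop response regeneration (None = keep assignment-based labels)
    response_coefficients: ResponseCoefficients | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cr < 2 or self.n_icr < 2:
            raise ValueError("need at least 2 samples per group")
        names = {g.name for g in self.gene_panel}
        if len(names) != len(self.gene_panel):
            raise ValueError("duplicate gene names in panel")
        for g in self.gene_panel:
            if not (0.0 < g.base_freq < 1.0):
                raise ValueError(f"base frequency of {g.name} outside (0,1)")
        seen: set[str] = set()
        for p in self.planted_pairs:
            for gene in (p.gene_a, p.gene_b):
                if gene not in names:
                    raise ValueError(f"planted pair references unknown gene {gene!r}")
                if gene in seen:
                    raise ValueError(f"gene {gene!r} appears in multiple planted pairs")
                seen.add(gene)
        if self.response_coefficients is not None:
            for gene in self.response_coefficients.network_genes:
                if gene not in names:
                    raise ValueError(f"network gene {gene!r} not in panel")

    @property
    def n_total(self) -> int:
        return self.n_cr + self.n_icr


@dataclass
class SyntheticTruth:
    """Everything the generator knew: the oracle for recovery tests."""

    params: SimulationParams
    clinical: pd.DataFrame
    assignment_logits: np.ndarray
    is_cr: np.ndarray
    gene_indicators: pd.DataFrame  # samples x panel genes, 0/1
    pair_counts: pd.Series  # per-sample count of planted pairs fully mutated
    n_decoys: int
    decoy_rows: np.ndarray  # row positions of decoys in the MAF frame
    response_probabilities: np.ndarray | None = None


def solve_latent_q(pa: float, pb: float, odds_ratio: float) -> float:
    """Latent-factor firing probability giving a target pair odds ratio.

    The pair model is X = L or A, Y = L or B with independent
    A ~ Bern(pa'), B ~ Bern(pb'), L ~ Bern(q), and pa', pb' chosen so
    the marginals stay at (pa, pb).  The induced odds ratio increases
    monotonically from 1 (q=0); q is solved by root finding.
    """
    if odds_ratio <= 1.0:
        raise ValueError("target odds ratio must exceed 1")
    qmax = min(pa, pb)

    def log_or(q: float) -> float:
        pa_r = 1.0 - (1.0 - pa) / (1.0 - q)
        pb_r = 1.0 - (1.0 - pb) / (1.0 - q)
        p11 = q + (1.0 - q) * pa_r * pb_r
        return math.log(p11) - math.log((1.0 - q) * pa_r * pb_r)

    lo, hi = 1e-9, qmax - 1e-9
    target = math.log(odds_ratio)
    if log_or(hi) < target:
        # requested dependence stronger than the marginals allow: saturate
        return hi
    return float(brentq(lambda q: log_or(q) - target, lo, hi, xtol=1e-12))


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _draw_covariates(params: SimulationParams, rng: np.random.Generator) -> pd.DataFrame:
    n = params.n_total
    age = rng.normal(params.age_mean, params.age_sd, n)
    bmi = rng.normal(params.bmi_mean, params.bmi_sd, n)
    female = rng.random(n) < params.p_female
    size = np.exp(rng.normal(math.log(params.tumor_size_median),
                             params.tumor_size_sigma, n))
    stage3 = rng.random(n) < params.p_stage3
    return pd.DataFrame({
        "age": np.round(age, 1),
        "bmi": np.round(bmi, 1),
        "gender": np.where(female, "female", "male"),
        "tumor_size": np.round(size, 2),
        "ajcc_stage": np.where(stage3, 3, 2),
    })


def _assignment_logits(cov: pd.DataFrame, coeffs: dict[str, float]) -> np.ndarray:
    z = {
        "age": _standardize(cov["age"].to_numpy(float)),
        "bmi": _standardize(cov["bmi"].to_numpy(float)),
        "gender_female": (cov["gender"] == "female").to_numpy(float),
        "tumor_size": _standardize(cov["tumor_size"].to_numpy(float)),
        "stage3": (cov["ajcc_stage"] == 3).to_numpy(float),
    }
    z["age_sq"] = z["age"] ** 2
    z["bmi_sq"] = z["bmi"] ** 2
    z["size_sq"] = z["tumor_size"] ** 2
    logits = np.zeros(len(cov))
    for key, c in coeffs.items():
        if key not in z:
            raise ValueError(f"unknown assignment covariate {key!r}")
        logits += c * z[key]
    return logits


def _assign_groups(logits: np.ndarray, n_cr: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Fixed group sizes with covariate-dependent acceptance.

    Plackett-Luce sampling: the n_cr largest Gumbel-perturbed logits
    become complete responders, i.e. selection probability is
    proportional to exp(logit).
    """
    gumbel = rng.gumbel(size=logits.size)
    order = np.argsort(-(logits + gumbel))
    is_cr = np.zeros(logits.size, dtype=bool)
    is_cr[order[:n_cr]] = True
    return is_cr


def _draw_gene_indicators(params: SimulationParams, is_cr: np.ndarray,
                          rng: np.random.Generator) -> pd.DataFrame:
    n = params.n_total
    panel = {g.name: g for g in params.gene_panel}
    paired = {p.gene_a for p in params.planted_pairs} | {
        p.gene_b for p in params.planted_pairs}
    out = {}
    for g in params.gene_panel:
        if g.name in paired:
            continue
        p = np.where(is_cr, g.group_freq(True), g.group_freq(False))
        out[g.name] = (rng.random(n) < p).astype(np.int8)
    for pair in params.planted_pairs:
        ga, gb = panel[pair.gene_a], panel[pair.gene_b]
        xa = np.zeros(n, dtype=np.int8)
        xb = np.zeros(n, dtype=np.int8)
        for grp in (True, False):
            mask = is_cr == grp
            m = int(mask.sum())
            if m == 0:
                continue
            pa, pb = ga.group_freq(grp), gb.group_freq(grp)
            q = solve_latent_q(pa, pb, math.exp(pair.log_or))
            pa_r = 1.0 - (1.0 - pa) / (1.0 - q)
            pb_r = 1.0 - (1.0 - pb) / (1.0 - q)
            latent = rng.random(m) < q
            xa[mask] = (latent | (rng.random(m) < pa_r)).astype(np.int8)
            xb[mask] = (latent | (rng.random(m) < pb_r)).astype(np.int8)
        out[pair.gene_a] = xa
        out[pair.gene_b] = xb
    cols = [g.name for g in params.gene_panel]
    return pd.DataFrame({c: out[c] for c in cols})


def _pair_counts(params: SimulationParams, ind: pd.DataFrame) -> pd.Series:
    counts = np.zeros(len(ind), dtype=int)
    for pair in params.planted_pairs:
        counts += (ind[pair.gene_a].to_numpy() & ind[pair.gene_b].to_numpy())
    return pd.Series(counts, name="pair_count")


def _regenerate_response(params: SimulationParams, cov: pd.DataFrame,
                         ind: pd.DataFrame, pair_counts: pd.Series,
                         rng: np.random.Generator):
    rc = params.response_coefficients
    net_genes = list(rc.network_genes)
    if net_genes:
        network = ind[net_genes].to_numpy().any(axis=1).astype(float)
    else:
        network = np.zeros(len(cov))
    cnt = pair_counts.to_numpy()
    lin = (rc.intercept
           + rc.tumor_size * cov["tumor_size"].to_numpy(float)
           + rc.stage3 * (cov["ajcc_stage"] == 3).to_numpy(float)
           + rc.network_gene * network
           + rc.cooccur_12 * ((cnt >= 1) & (cnt <= 2))
           + rc.cooccur_3plus * (cnt >= 3))
    p = expit(lin)
    return (rng.random(len(cov)) < p), p


def _truncated_beta_af(rng: np.random.Generator, size: int,
                       lower: float = 0.1) -> np.ndarray:
    """Beta(5,5) allele fractions conditioned on exceeding the filter cutoff."""
    flo = beta_dist.cdf(lower, 5, 5)
    u = flo + (1.0 - flo) * rng.random(size)
    return beta_dist.ppf(u, 5, 5)


def _emit_maf(params: SimulationParams, sample_ids: list[str], is_cr: np.ndarray,
              ind: pd.DataFrame, rng: np.random.Generator):
    """MAF rows for panel hits, passenger mutations, and sub-threshold decoys."""
    rows_sample, rows_gene = [], []
    # panel hits
    for gene in ind.columns:
        hit = np.flatnonzero(ind[gene].to_numpy())
        rows_sample.extend(hit)
        rows_gene.extend([gene] * hit.size)
    # passengers: bring per-sample totals up to the group TMB means
    panel_mean = np.where(is_cr,
                          sum(g.group_freq(True) for g in params.gene_panel),
                          sum(g.group_freq(False) for g in params.gene_panel))
    lam = np.maximum(np.where(is_cr, params.tmb_mean_cr, params.tmb_mean_icr)
                     - panel_mean, 0.1)
    n_extra = rng.poisson(lam)
    passenger_names = np.array(
        [f"PSG{i:04d}" for i in range(1, params.n_passenger_genes + 1)])
    for i, k in enumerate(n_extra):
        if k:
            rows_sample.extend([i] * int(k))
            rows_gene.extend(passenger_names[rng.integers(
                0, params.n_passenger_genes, int(k))])
    n_retained = len(rows_sample)
    # decoys: sub-threshold depth or allele fraction
    n_decoys = int(round(params.decoy_fraction * n_retained))
    decoy_sample = rng.integers(0, params.n_total, n_decoys)
    decoy_gene = passenger_names[rng.integers(0, params.n_passenger_genes, n_decoys)]
    rows_sample.extend(decoy_sample)
    rows_gene.extend(decoy_gene)
    n_rows = len(rows_sample)

    depth = 30 + rng.poisson(max(params.depth_mean - 30.0, 1.0), n_rows)
    af = np.round(_truncated_beta_af(rng, n_rows), 4)
    # overwrite the decoy tail with sub-threshold values
    decoy_rows = np.arange(n_retained, n_rows)
    low_depth = rng.random(n_decoys) < 0.5
    depth[decoy_rows[low_depth]] = rng.integers(5, 30, int(low_depth.sum()))
    af[decoy_rows[~low_depth]] = np.round(
        0.005 + 0.09 * rng.random(int((~low_depth).sum())), 4)

    classes = rng.choice(_CLASS_CHOICES, size=n_rows, p=_CLASS_PROBS)
    positions = rng.integers(1, 100_000, n_rows)
    ref = rng.choice(_BASES, size=n_rows)
    alt_shift = rng.integers(1, 4, n_rows)
    alt = np.array(_BASES)[(np.searchsorted(_BASES, ref) + alt_shift) % 4]
    maf = pd.DataFrame({
        "Hugo_Symbol": rows_gene,
        "Chromosome": [f"ctg_{g}" for g in rows_gene],
        "Start_Position": positions,
        "Reference_Allele": ref,
        "Tumor_Seq_Allele2": alt,
        "Variant_Classification": classes,
        "Tumor_Sample_Barcode": [sample_ids[i] for i in rows_sample],
        "t_depth": depth,
        "AF": af,
    }, columns=MAF_COLUMNS)
    return maf, decoy_rows


def simulate_cohort(params: SimulationParams, emit_maf: bool = True):
    """Draw one synthetic cohort.

    Returns ``(clinical, maf, truth)``: the clinical table, a MAF-style
    DataFrame (empty when ``emit_maf`` is False, which skips the costly
    variant-level emission for matrix-only studies), and the
    :class:`SyntheticTruth` oracle.
    """
    rng = np.random.default_rng(params.seed)
    cov = _draw_covariates(params, rng)
    logits = _assignment_logits(cov, params.assignment_coefficients)
    is_cr = _assign_groups(logits, params.n_cr, rng)
    ind = _draw_gene_indicators(params, is_cr, rng)
    counts = _pair_counts(params, ind)
    probs = None
    if params.response_coefficients is not None:
        is_cr, probs = _regenerate_response(params, cov, ind, counts, rng)
    sample_ids = [f"S{i + 1:04d}" for i in range(params.n_total)]
    clinical = cov.copy()
    clinical.insert(0, "sample_id", sample_ids)
    clinical.insert(1, "response", np.where(is_cr, "CR", "ICR"))
    clinical["t_stage"] = np.where(clinical["ajcc_stage"] == 3, "T3", "T2")
    clinical["n_stage"] = np.where(
        rng.random(params.n_total) < np.where(is_cr, 0.70, 0.79), "N+", "N0")
    clinical["recurrence"] = np.where(
        rng.random(params.n_total) < np.where(is_cr, 0.10, 0.30), "yes", "no")
    clinical["msi_status"] = np.where(
        rng.random(params.n_total) < 0.02, "MSI-H", "MSS")
    ind.index = pd.Index(sample_ids, name="sample_id")
    counts.index = ind.index
    if emit_maf:
        maf, decoy_rows = _emit_maf(params, sample_ids, is_cr, ind, rng)
    else:
        maf = pd.DataFrame(columns=MAF_COLUMNS)
        decoy_rows = np.array([], dtype=int)
    truth = SyntheticTruth(params=params, clinical=clinical,
                           assignment_logits=logits, is_cr=np.asarray(is_cr),
                           gene_indicators=ind, pair_counts=counts,
                           n_decoys=decoy_rows.size, decoy_rows=decoy_rows,
                           response_probabilities=probs)
    return clinical, maf, truth


def truth_matrix(truth: SyntheticTruth) -> MutationMatrix:
    """Panel-gene mutation matrix straight from the generator's truth
    (bypasses MAF emission and filtering)."""
    ind = truth.gene_indicators
    genes = list(ind.columns)
    freq = ind.to_numpy().sum(axis=0)
    order = sorted(range(len(genes)), key=lambda j: (-freq[j], genes[j]))
    return MutationMatrix(list(ind.index), [genes[j] for j in order],
                          ind.to_numpy()[:, order])


def records_from_frame(maf: pd.DataFrame) -> list[VariantRecord]:
    """Convert an in-memory MAF frame to validated variant records."""
    return [VariantRecord(
        sample_id=str(r.Tumor_Sample_Barcode), gene=str(r.Hugo_Symbol),
        chromosome=str(r.Chromosome), position=int(r.Start_Position),
        ref_allele=str(r.Reference_Allele), alt_allele=str(r.Tumor_Seq_Allele2),
        variant_classification=str(r.Variant_Classification),
        depth=int(r.t_depth), allele_fraction=float(r.AF),
    ) for r in maf.itertuples(index=False)]


def preset(name: str, seed: int = 0, **overrides) -> SimulationParams:
    """Named study conditions.

    - ``paperlike``: the reference 364-patient confounded cohort.
    - ``null``: no group effects, no confounding, no planted pairs.
    - ``strong-confounding``: 400 patients whose CR assignment depends
      strongly on age, BMI, gender and tumor size.
    - ``planted-pairs``: unconfounded cohort emphasizing co-occurring
      pair structure.
    - ``closed-loop``: response regenerated from known logistic
      coefficients (Table-1 scale) for whole-pipeline recovery checks.
    """
    if name == "paperlike":
        params = SimulationParams(seed=seed)
    elif name == "null":
        panel = tuple(GeneSpec(g.name, g.base_freq, 0.0)
                      for g in _default_gene_panel())
        params = SimulationParams(
            gene_panel=panel, planted_pairs=(),
            assignment_coefficients={}, tmb_mean_cr=9.0, tmb_mean_icr=9.0,
            seed=seed)
    elif name == "strong-confounding":
        params = SimulationParams(
            n_cr=120, n_icr=280,
            assignment_coefficients={"age": 0.55, "bmi": 0.55,
                                     "gender_female": 0.70, "tumor_size": -0.80},
            seed=seed)
    elif name == "closed-loop":
        # response regenerated from known logistic coefficients: the
        # recovery benchmark for the full screening/fitting pipeline
        n_pairs = 8
        pair_genes = [f"PRG{i:02d}" for i in range(2 * n_pairs)]
        net_genes = [f"NWG{i:02d}" for i in range(6)]
        panel = tuple([GeneSpec(g, 0.35) for g in pair_genes]
                      + [GeneSpec(g, 0.15) for g in net_genes])
        pairs = tuple(PlantedPair(pair_genes[2 * i], pair_genes[2 * i + 1],
                                  math.log(8.0)) for i in range(n_pairs))
        rc = ResponseCoefficients(intercept=-0.9,
                                  cooccur_3plus=math.log(8.47),
                                  network_genes=tuple(net_genes))
        params = SimulationParams(
            gene_panel=panel, planted_pairs=pairs,
            assignment_coefficients={}, response_coefficients=rc,
            tmb_mean_cr=9.0, tmb_mean_icr=9.0, seed=seed)
    elif name == "planted-pairs":
        params = SimulationParams(
            assignment_coefficients={},
            planted_pairs=(
                PlantedPair("MSH3", "POLE", math.log(8.0)),
                PlantedPair("BRCA1", "BARD1", math.log(8.0)),
                PlantedPair("MLH1", "PMS1", math.log(8.0)),
            ),
            seed=seed)
    else:
        raise ValueError(f"unknown preset {name!r}")
    return replace(params, **overrides) if overrides else params


def _params_toml(params: SimulationParams) -> str:
    lines = ["[simulation]"]
    for key in ("n_cr", "n_icr", "age_mean", "age_sd", "bmi_mean", "bmi_sd",
                "p_female", "tumor_size_median", "tumor_size_sigma", "p_stage3",
                "tmb_mean_cr", "tmb_mean_icr", "coding_length_mb",
                "n_passenger_genes", "decoy_fraction", "depth_mean", "seed"):
        lines.append(f"{key} = {getattr(params, key)}")
    lines.append("\n[assignment_coefficients]")
    for k, v in params.assignment_coefficients.items():
        lines.append(f"{k} = {v}")
    lines.append("\n[[gene_panel]]" if params.gene_panel else "")
    lines.pop()
    for g in params.gene_panel:
        lines += ["\n[[gene_panel]]", f'name = "{g.name}"',
                  f"base_freq = {g.base_freq}", f"log_or = {g.log_or}"]
    for p in params.planted_pairs:
        lines += ["\n[[planted_pairs]]", f'gene_a = "{p.gene_a}"',
                  f'gene_b = "{p.gene_b}"', f"log_or = {p.log_or}"]
    return "\n".join(lines) + "\n"


def write_fixture_bundle(path, params: SimulationParams,
                         overwrite: bool = False) -> dict[str, Path]:
    """Write clinical TSV, MAF, truth sidecars and the params file.

    Re-running with identical params (including seed) reproduces the
    files byte for byte.
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "clinical": out / "clinical.tsv",
        "maf": out / "mutations.maf",
        "truth_genes": out / "truth_gene_indicators.tsv",
        "truth_samples": out / "truth_samples.tsv",
        "params": out / "params.toml",
    }
    if not overwrite:
        existing = [str(f) for f in files.values() if f.exists()]
        if existing:
            raise FileExistsError(
                f"refusing to overwrite {existing}; pass overwrite=True")
    clinical, maf, truth = simulate_cohort(params)
    clinical.to_csv(files["clinical"], sep="\t", index=False)
    maf.to_csv(files["maf"], sep="\t", index=False)
    truth.gene_indicators.to_csv(files["truth_genes"], sep="\t")
    sidecar = pd.DataFrame({
        "sample_id": clinical["sample_id"],
        "assignment_logit": np.round(truth.assignment_logits, 6),
        "is_cr": truth.is_cr.astype(int),
        "pair_count": truth.pair_counts.to_numpy(),
    })
    if truth.response_probabilities is not None:
        sidecar["response_probability"] = np.round(truth.response_probabilities, 6)
    sidecar.to_csv(files["truth_samples"], sep="\t", index=False)
    files["params"].write_text(_params_toml(params))
    return files


def bundle_checksum(files: dict[str, Path]) -> str:
    """SHA-256 over the bundle contents, for determinism checks."""
    h = hashlib.sha256()
    for key in sorted(files):
        h.update(files[key].read_bytes())
    return h.hexdigest()
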