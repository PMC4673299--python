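"""Synthetic paired tumor/normal cohorts with planted structure.

The generator emulates the study design the pipeline targets: a small
paired cohort (three tumor/normal pairs by default) profiled on a mixed
lncRNA/mRNA log2 expression array.  Planted structure — differential
probes, co-expression modules, annotation terms and TF target sets tied
to modules, and qPCR measurements of selected probes — is recorded in a
:class:`SyntheticTruth` so every downstream stage can be scored against
ground truth.

Model, per probe and sample (log2 scale):

* background probe: ``baseline_i + patient_effect_{i,p} + noise``,
* differential probe: adds ``sign_i * (de_effect_log2 + patient
  heterogeneity)`` to its tumor samples — tumors differ in effect
  magnitude patient to patient (``de_patient_sd``), which keeps
  unrelated strongly-differential probes from correlating perfectly
  through the shared tumor/normal split,
* module member: shares its module's latent patient trajectory (one
  value per patient, applied to both of that patient's samples — the
  module tracks patient-level biology) and the module's common tumor
  shift, plus a small private residual (``module_noise_sd``), yielding
  near-collinear within-module profiles (|r| >= 0.99 across six
  samples) while distinct modules and background differential probes
  stay below the edge threshold.  Because patient-level terms cancel
  in the tumor-minus-normal contrast, module members remain easy to
  detect as differential despite their shared variability.

Detection flags are "A" below ``flag_absent_threshold``, "P" otherwise.
All randomness flows from a single integer seed; identical
``(params, seed)`` reproduce outputs bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .io_formats import (DesignEntry, ExpressionMatrix, GeneSetCollection,
                         ProbeAnnotation, StudyDesign)


@dataclass
class SimulationParams:
    """Knobs of the synthetic cohort; defaults are the study conditions."""

    n_lncrna: int = 1000
    n_mrna: int = 1000
    n_patients: int = 3
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    patient_sd: float = 0.5          # per probe-patient baseline shift
    noise_sd: float = 0.5
    de_fraction: float = 0.03        # of non-module probes
    de_effect_log2: float = 3.0
    de_patient_sd: float = 0.2       # between-patient effect heterogeneity
    n_modules: int = 3
    module_size: int = 20            # half lncRNA, half mRNA
    module_amplitude: float = 0.5    # latent per-patient trajectory sd
    module_noise_sd: float = 0.04
    flag_absent_threshold: float = 1.0
    # annotation geometry
    n_chromosomes: int = 22
    gene_length: int = 1000
    gene_spacing: int = 200_000
    cis_fraction: float = 0.2        # module mRNAs placed <100 kb from an lncRNA
    # gene-set collections
    n_terms: int = 30
    n_tfs: int = 20
    set_size: int = 50
    # qPCR
    qpcr_n_patients: int = 12
    qpcr_replicates: int = 3
    ct_noise_sd: float = 0.1
    qpcr_patient_sd: float = 0.25    # biological spread of the effect per patient
    reference_ct: float = 18.0
    target_ct_normal: float = 26.0

    def __post_init__(self) -> None:
        for name in ("n_lncrna", "n_mrna", "n_patients", "n_modules",
                     "module_size", "n_terms", "n_tfs", "set_size",
                     "qpcr_n_patients", "qpcr_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("baseline_sd", "patient_sd", "noise_sd", "de_patient_sd",
                     "module_amplitude", "module_noise_sd", "ct_noise_sd",
                     "qpcr_patient_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("de_fraction", "cis_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Everything planted, for scoring recovery downstream."""

    de_probes: dict[str, float]          # probe -> signed log2 effect
    module_assignment: dict[str, int]    # probe -> module (0 = background)
    tf_links: dict[str, int] = field(default_factory=dict)
    term_links: dict[str, int] = field(default_factory=dict)
    all_probes: list[str] = field(default_factory=list)
    seed: int = 0

    def module_members(self, module: int,
                       biotype: str | None = None) -> list[str]:
        out = [p for p, m in self.module_assignment.items() if m == module]
        if biotype == "lncRNA":
            out = [p for p in out if p.startswith("LNC")]
        elif biotype == "mRNA":
            out = [p for p in out if p.startswith("MRNA")]
        return out


def _module_latents(rng: np.random.Generator, n_modules: int, n_pat: int,
                    amplitude: float) -> np.ndarray:
    """Latent sample trajectories, one row per module.

    Rows live in the orthogonal complement of the intercept and the
    tumor indicator (dimension 2*n_pat - 2), are mutually orthogonal up
    to that dimension, and each has per-sample standard deviation equal
    to ``amplitude``.
    """
    from scipy.linalg import null_space

    n_samples = 2 * n_pat
    out = np.zeros((n_modules, n_samples))
    if amplitude == 0 or n_samples < 3:
        return out
    t = np.zeros(n_samples)
    t[:n_pat] = 1.0
    basis = null_space(np.vstack([np.ones(n_samples), t]))  # (2n, 2n-2)
    dim = basis.shape[1]
    raw = basis @ rng.normal(size=(dim, n_modules))
    # Gram-Schmidt across modules; beyond the space dimension the extra
    # rows stay random (orthogonality is impossible there)
    q, _ = np.linalg.qr(raw[:, :min(n_modules, dim)])
    raw[:, :q.shape[1]] = q
    sd = raw.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (raw / sd * amplitude).T


def _probe_ids(params: SimulationParams) -> tuple[list[str], list[str]]:
    lnc = [f"LNC{i:05d}" for i in range(params.n_lncrna)]
    mrna = [f"MRNA{i:05d}" for i in range(params.n_mrna)]
    return lnc, mrna


def generate_expression(params: SimulationParams, seed: int
                        ) -> tuple[ExpressionMatrix, StudyDesign,
                                   SyntheticTruth]:
    """Simulate the paired cohort; see the module docstring for the model."""
    per_side = params.n_modules * (params.module_size // 2
                                   + params.module_size % 2)
    if per_side > min(params.n_lncrna, params.n_mrna):
        raise ValueError("module probes exceed available probe count")
    rng = np.random.default_rng(seed)
    lnc_ids, mrna_ids = _probe_ids(params)
    probes = lnc_ids + mrna_ids
    n_probes = len(probes)
    n_pat = params.n_patients
    samples = [f"C{i + 1}" for i in range(n_pat)] + \
              [f"N{i + 1}" for i in range(n_pat)]
    design = StudyDesign(
        [DesignEntry(f"C{i + 1}", f"patient{i + 1}", "tumor")
         for i in range(n_pat)]
        + [DesignEntry(f"N{i + 1}", f"patient{i + 1}", "normal")
           for i in range(n_pat)])

    # module membership: split each module half lncRNA / half mRNA
    half = params.module_size // 2 + params.module_size % 2
    lnc_pick = rng.choice(params.n_lncrna,
                          size=params.n_modules * half, replace=False)
    mrna_pick = rng.choice(params.n_mrna,
                           size=params.n_modules * (params.module_size - half),
                           replace=False)
    module_assignment = {p: 0 for p in probes}
    for m in range(params.n_modules):
        for i in lnc_pick[m * half:(m + 1) * half]:
            module_assignment[lnc_ids[i]] = m + 1
        lo, hi = m * (params.module_size - half), \
            (m + 1) * (params.module_size - half)
        for i in mrna_pick[lo:hi]:
            module_assignment[mrna_ids[i]] = m + 1

    # differential probes: every module member, plus a background fraction
    module_sign = rng.choice([-1.0, 1.0], size=params.n_modules)
    de_probes: dict[str, float] = {}
    for p, m in module_assignment.items():
        if m > 0:
            de_probes[p] = module_sign[m - 1] * params.de_effect_log2
    background = [p for p in probes if module_assignment[p] == 0]
    n_bg_de = int(round(params.de_fraction * len(background)))
    bg_de = rng.choice(len(background), size=n_bg_de, replace=False)
    bg_sign = rng.choice([-1.0, 1.0], size=n_bg_de)
    for i, s in zip(bg_de, bg_sign):
        de_probes[background[i]] = s * params.de_effect_log2

    baseline = rng.normal(params.baseline_mean, params.baseline_sd, n_probes)
    # Differential probes are planted at mid-range intensities (within
    # one baseline_sd of the mean) so that the shifted condition stays
    # inside the simulated dynamic range of the array; effects planted
    # in the tails would be censored by rank-based normalization, as on
    # a real array where they would leave the linear response range.
    if de_probes:
        de_idx = [i for i, p in enumerate(probes) if p in de_probes]
        mid = truncnorm.rvs(-1.0, 1.0, loc=params.baseline_mean,
                            scale=params.baseline_sd, size=len(de_idx),
                            random_state=rng)
        baseline[de_idx] = mid
    patient_effect = rng.normal(0.0, params.patient_sd, (n_probes, n_pat))
    # Per-module latent trajectories across the 2*n_pat samples.  Drawn
    # inside the orthogonal complement of {intercept, tumor indicator},
    # orthogonalized across modules and scaled to exactly
    # module_amplitude: modules then decorrelate from one another and
    # from the tumor contrast by construction, and the latent's
    # contribution to the pooled within-group variance is fixed rather
    # than a heavy-tailed draw of the small patient count.
    module_latent = _module_latents(rng, params.n_modules, n_pat,
                                    params.module_amplitude)
    module_de_jitter = rng.normal(0.0, params.de_patient_sd,
                                  (params.n_modules, n_pat))
    probe_de_jitter = rng.normal(0.0, params.de_patient_sd, (n_probes, n_pat))

    tumor = np.zeros(2 * n_pat, dtype=bool)
    tumor[:n_pat] = True
    patient_of = np.concatenate([np.arange(n_pat), np.arange(n_pat)])
    values = np.empty((n_probes, 2 * n_pat))
    probe_index = {p: i for i, p in enumerate(probes)}
    for p in probes:
        i = probe_index[p]
        m = module_assignment[p]
        effect = de_probes.get(p, 0.0)
        if m > 0:
            row = baseline[i] + module_latent[m - 1]
            shift = effect + np.sign(effect) * module_de_jitter[m - 1]
            row = row + np.where(tumor, shift[patient_of], 0.0)
            row = row + rng.normal(0.0, params.module_noise_sd, 2 * n_pat)
        else:
            row = baseline[i] + patient_effect[i, patient_of]
            if effect != 0.0:
                shift = effect + np.sign(effect) * probe_de_jitter[i]
                row = row + np.where(tumor, shift[patient_of], 0.0)
            row = row + rng.normal(0.0, params.noise_sd, 2 * n_pat)
        values[i] = row

    flags = np.where(values < params.flag_absent_threshold, "A", "P"
                     ).astype("<U1")
    matrix = ExpressionMatrix(probes, samples, values, flags)
    truth = SyntheticTruth(de_probes, module_assignment,
                           all_probes=list(probes), seed=seed)
    return matrix, design, truth


def generate_annotation(params: SimulationParams, seed: int,
                        truth: SyntheticTruth | None = None
                        ) -> list[ProbeAnnotation]:
    """Assign each probe a non-overlapping genomic span.

    Probes are laid out round-robin over ``n_chromosomes`` chromosomes
    at ``gene_spacing`` intervals (> 100 kb by default, so arbitrary
    pairs are trans).  When a truth with modules is supplied, a
    ``cis_fraction`` of each module's mRNAs is relocated to within
    100 kb of the module's first lncRNA, exercising the cis branch of
    the distance rule.
    """
    rng = np.random.default_rng(seed)
    lnc_ids, mrna_ids = _probe_ids(params)
    probes = lnc_ids + mrna_ids
    records: dict[str, ProbeAnnotation] = {}
    for idx, p in enumerate(probes):
        chrom = f"chr{idx % params.n_chromosomes + 1}"
        start = (idx // params.n_chromosomes) * params.gene_spacing
        biotype = "lncRNA" if p.startswith("LNC") else "mRNA"
        records[p] = ProbeAnnotation(p, p, biotype, chrom, start,
                                     start + params.gene_length,
                                     "+" if rng.random() < 0.5 else "-")
    if truth is not None and params.cis_fraction > 0:
        modules = sorted({m for m in truth.module_assignment.values()
                          if m > 0})
        for m in modules:
            lncs = truth.module_members(m, "lncRNA")
            mrnas = truth.module_members(m, "mRNA")
            if not lncs or not mrnas:
                continue
            anchor = records[lncs[0]]
            n_cis = int(round(params.cis_fraction * len(mrnas)))
            for j, mp in enumerate(mrnas[:n_cis]):
                # 2 kb steps keep every relocated gene within 100 kb
                start = anchor.end + 2000 * (j + 1)
                records[mp] = ProbeAnnotation(
                    mp, mp, "mRNA", anchor.chrom, start,
                    start + params.gene_length, records[mp].strand)
    return [records[p] for p in probes]


def generate_gene_sets(truth: SyntheticTruth, params: SimulationParams,
                       seed: int
                       ) -> tuple[GeneSetCollection, GeneSetCollection]:
    """Annotation terms and TF target sets over the mRNA universe.

    One term and one TF per module are linked: their membership is the
    module's mRNAs padded with random background mRNAs up to
    ``set_size``.  Remaining sets are uniform random draws.  Links are
    recorded in ``truth.term_links`` / ``truth.tf_links``.
    """
    rng = np.random.default_rng(seed)
    _, mrna_ids = _probe_ids(params)
    universe = np.array(mrna_ids)
    modules = sorted({m for m in truth.module_assignment.values() if m > 0})

    def build(prefix: str, count: int, links: dict[str, int]
              ) -> GeneSetCollection:
        sets: dict[str, frozenset[str]] = {}
        descriptions: dict[str, str] = {}
        for i in range(count):
            sid = f"{prefix}{i:03d}"
            if i < len(modules):
                m = modules[i]
                members = truth.module_members(m, "mRNA")
                if params.set_size < len(members):
                    raise ValueError(
                        f"set_size {params.set_size} < module mRNA count "
                        f"{len(members)}")
                pool = np.array([g for g in universe
                                 if truth.module_assignment.get(g, 0) != m])
                extra = rng.choice(pool, params.set_size - len(members),
                                   replace=False)
                sets[sid] = frozenset(members) | frozenset(extra.tolist())
                links[sid] = m
                descriptions[sid] = f"linked to module {m}"
            else:
                draw = rng.choice(universe, params.set_size, replace=False)
                sets[sid] = frozenset(draw.tolist())
                descriptions[sid] = "background set"
        return GeneSetCollection(sets, descriptions)

    truth.term_links = {}
    truth.tf_links = {}
    terms = build("TERM", params.n_terms, truth.term_links)
    tfs = build("TF", params.n_tfs, truth.tf_links)
    return terms, tfs


def default_validation_probes(truth: SyntheticTruth, seed: int,
                              n: int = 4) -> list[str]:
    """Pick differential probes for qPCR validation (balanced up/down)."""
    rng = np.random.default_rng(seed)
    up = sorted(p for p, e in truth.de_probes.items() if e > 0)
    down = sorted(p for p, e in truth.de_probes.items() if e < 0)
    picks: list[str] = []
    for pool in (up, down):
        if pool:
            take = min(n - len(picks), max(1, n // 2), len(pool))
            picks += rng.choice(pool, take, replace=False).tolist()
    return picks[:n]


def generate_qpcr(truth: SyntheticTruth, params: SimulationParams, seed: int,
                  probe_ids: list[str] | None = None,
                  reference_gene: str = "GAPDH") -> pd.DataFrame:
    """Triplicate Ct tables for selected probes over an independent cohort.

    For each probe with planted log2 effect ``e`` the expected
    tumor-vs-normal ddCt is ``-e`` (so the recovered fold change is
    ``2^e``); per patient the effect receives biological jitter
    ``qpcr_patient_sd`` and every replicate Gaussian Ct noise
    ``ct_noise_sd``.  The reference gene is condition-independent in
    expectation.
    """
    rng = np.random.default_rng(seed)
    if probe_ids is None:
        probe_ids = default_validation_probes(truth, seed)
    known = set(truth.all_probes)
    unknown = [p for p in probe_ids if p not in known]
    if unknown:
        raise ValueError(f"probes not in truth: {unknown}")
    rows = []
    reps = params.qpcr_replicates

    def emit(patient: str, condition: str, gene: str, mean_ct: float) -> None:
        cts = mean_ct + rng.normal(0.0, params.ct_noise_sd, reps)
        rows.append([patient, condition, gene] + [float(c) for c in cts])

    for i in range(params.qpcr_n_patients):
        patient = f"vpatient{i + 1}"
        for probe in probe_ids:
            effect = truth.de_probes.get(probe, 0.0)
            patient_effect = effect + (rng.normal(0.0, params.qpcr_patient_sd)
                                       if effect != 0 else 0.0)
            # higher expression -> lower Ct
            emit(patient, "tumor", probe,
                 params.target_ct_normal - patient_effect)
            emit(patient, "normal", probe, params.target_ct_normal)
        emit(patient, "tumor", reference_gene, params.reference_ct)
        emit(patient, "normal", reference_gene, params.reference_ct)
    cols = ["patient_id", "condition", "gene_id"] + \
        [f"ct_rep{r + 1}" for r in range(reps)]
    return pd.DataFrame(rows, columns=cols)
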