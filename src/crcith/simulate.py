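"""Synthetic multiregional cohort generator with known ground truth.

Emulates the structure of a multiregional colorectal-cancer expression
study: ~100 primary tumors with 2-4 spatially distinct samples each, a
per-gene two-level variance structure (between-tumor random effect +
within-tumor residual), four latent subtypes (CMS1-4) expressed through
planted template genes, an MSI-like superclass axis nesting the four
classes into two, a stromal-infiltration confounder that makes a subset of
genes heterogeneous within tumors, subtype-mixture (heterogeneous) tumors,
MSI labels correlated with subtype, and right-censored relapse-free
survival with subtype- and heterogeneity-dependent hazards.

Every planted quantity is returned in :class:`TruthTables` so downstream
estimators can be scored against ground truth.

The expression model for gene ``g`` in sample ``s`` of tumor ``t`` is::

    x[g, s] = mu_g
            + sum_c  tpl[g, c] * w_s(c)        # signed template effects
            + stromal_scale[g] * infil_s       # infiltration confounder
            + u[g, t]                          # N(0, sigma_tumor_sq[g])
            + e[g, s]                          # N(0, sigma_resid_sq[g])

where ``w_s`` are the per-sample class weights (a point mass for samples
of homogeneous tumors; a major/minor mixture for samples of heterogeneous
tumors) and ``infil_s ~ Uniform(0, 1)`` independently of tumor, so stromal
genes are intra-tumor-heterogeneous by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .io import Cohort, ExpressionMatrix, validate_sample_sheet

CLASSES = ("CMS1", "CMS2", "CMS3", "CMS4")

#: Minor-class pairing observed for heterogeneous tumors: CMS2/4 and CMS1/3
#: are the common combinations, with CMS4 and CMS3 as minor components.
DEFAULT_MINOR_PAIRING = {"CMS1": "CMS3", "CMS2": "CMS4", "CMS3": "CMS1", "CMS4": "CMS2"}

#: Gene-category variance profile: (sigma_tumor_sq, sigma_resid_sq).
DEFAULT_VARIANCE_PROFILE = {
    "template": (0.40, 0.10),
    "superclass": (0.40, 0.10),
    "stromal": (0.05, 0.30),
    "background_low": (0.50, 0.10),
    "background_intermediate": (0.18, 0.32),
    "background_high": (0.05, 0.45),
    "flat": (0.02, 0.05),
}

#: Background gene counts chosen so that, after the 10-90th percentile
#: range filter, the low/intermediate/high category proportions are close
#: to the ~48/48/5 per-cent split seen in multiregional tumor data.
DEFAULT_BACKGROUND_COUNTS = {
    "background_low": 210,
    "background_intermediate": 690,
    "background_high": 25,
}


@dataclass(frozen=True)
class SurvivalModel:
    """Exponential relapse-free-survival model (rates per month)."""

    baseline_hazard: float = 0.0015
    #: log hazard offsets per subtype, reference CMS1 (HRs ~3.7/2.3/4.3).
    subtype_log_hr: Tuple[float, float, float, float] = (0.0, 1.308, 0.833, 1.459)
    heterogeneity_log_hr: float = 0.470  # HR ~1.6 for mixed tumors
    censoring_rate: float = 0.005
    admin_censor_months: float = 120.0


@dataclass(frozen=True)
class SimulationConfig:
    n_tumors: int = 100
    #: distribution over the number of spatially distinct samples per tumor
    #: (mean 2.9 under the default, matching multiregional sampling depth).
    samples_per_tumor: Dict[int, float] = field(
        default_factory=lambda: {2: 0.3, 3: 0.5, 4: 0.2}
    )
    n_genes: int = 2000
    subtype_proportions: Tuple[float, float, float, float] = (0.25, 0.30, 0.25, 0.20)
    het_fraction: float = 0.4
    #: fraction of a heterogeneous tumor's samples assigned the minor class
    minor_sample_fraction: float = 0.35
    #: within-sample admixture of the non-assigned class in heterogeneous
    #: tumors (bulk regions of a mixed tumor are never clonally pure)
    admixture: float = 0.35
    template_genes_per_class: int = 100
    template_log2fc: float = 2.0
    #: per-class multiplier on template_log2fc; CMS1/CMS3 (the MSI-like
    #: superclass) are transcriptionally closer to each other than
    #: CMS2/CMS4 are, which makes low-rank merges data-determined
    class_lfc_scale: Tuple[float, float, float, float] = (0.7, 1.0, 0.7, 1.0)
    superclass_genes: int = 80
    superclass_log2fc: float = 1.2
    stromal_genes: int = 40
    stromal_effect_scale: float = 1.5
    variance_profile: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_VARIANCE_PROFILE)
    )
    background_counts: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND_COUNTS)
    )
    msi_prob_by_class: Tuple[float, float, float, float] = (0.75, 0.02, 0.25, 0.05)
    minor_pairing: Dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_MINOR_PAIRING)
    )
    survival: SurvivalModel = field(default_factory=SurvivalModel)
    baseline_mean: float = 7.0
    baseline_mean_sd: float = 1.0
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-9:
            raise ValueError("subtype_proportions must sum to 1")
        if abs(sum(self.samples_per_tumor.values()) - 1.0) > 1e-9:
            raise ValueError("samples_per_tumor probabilities must sum to 1")
        if not 0.0 <= self.het_fraction <= 1.0:
            raise ValueError("het_fraction must be in [0, 1]")
        for cat, (a, b) in self.variance_profile.items():
            if a < 0 or b < 0:
                raise ValueError(f"negative variance for category {cat!r}")
        n_structured = (
            4 * self.template_genes_per_class
            + self.superclass_genes
            + self.stromal_genes
            + sum(self.background_counts.values())
        )
        if n_structured > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for the configured "
                f"structured genes ({n_structured})"
            )
        if (
            self.het_fraction > 0
            and set(self.samples_per_tumor) == {1}
            and self.admixture == 0
        ):
            raise ValueError(
                "het_fraction > 0 with one pure sample per tumor leaves "
                "heterogeneity unrepresentable; set admixture > 0 or "
                "samples_per_tumor >= 2"
            )
        return self


@dataclass
class TruthTables:
    """Ground truth for a simulated cohort."""

    genes: pd.DataFrame  # gene_id, category, sigmas, template class/direction
    tumors: pd.DataFrame  # tumor_id, major/minor class, heterogeneous, msi
    samples: pd.DataFrame  # sample_id, assigned class, class weights, infiltration
    patients: pd.DataFrame  # patient_id, true log hazard, time, event
    metastasis_pairs: Optional[pd.DataFrame] = None


def _assign_gene_categories(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    g = 0

    def add(n, category, **kw):
        nonlocal g
        st, se = config.variance_profile[category]
        for _ in range(n):
            rows.append(
                dict(
                    gene_id=f"G{g:05d}",
                    category=category,
                    sigma_tumor_sq=st,
                    sigma_resid_sq=se,
                    template_class=kw.get("template_class"),
                    template_direction=kw.get("direction"),
                    stromal=category == "stromal",
                )
            )
            g += 1

    half = config.template_genes_per_class // 2
    for c in CLASSES:
        add(half, "template", template_class=c, direction="up")
        add(config.template_genes_per_class - half, "template", template_class=c, direction="down")
    s_half = config.superclass_genes // 2
    add(s_half, "superclass", direction="up")  # up in {CMS2, CMS4}
    add(config.superclass_genes - s_half, "superclass", direction="down")
    add(config.stromal_genes, "stromal")
    for cat, n in config.background_counts.items():
        add(n, cat)
    n_flat = config.n_genes - g
    add(n_flat, "flat")
    df = pd.DataFrame(rows)
    # effective within-tumor variance includes the infiltration effect,
    # Var(scale * U(0,1)) = scale^2 / 12
    extra = np.where(df["stromal"], config.stromal_effect_scale**2 / 12.0, 0.0)
    df["sigma_resid_sq_effective"] = df["sigma_resid_sq"] + extra
    df["true_icc"] = df["sigma_tumor_sq"] / (
        df["sigma_tumor_sq"] + df["sigma_resid_sq_effective"]
    )
    df["true_ith_score"] = 1.0 - df["true_icc"]
    return df


def _template_effect_matrix(genes: pd.DataFrame, config: SimulationConfig) -> np.ndarray:
    """Signed log2 effect of each class on each gene (n_genes x 4)."""
    tpl = np.zeros((len(genes), 4))
    scale = dict(zip(CLASSES, config.class_lfc_scale))
    for i, row in enumerate(genes.itertuples(index=False)):
        if row.category == "template":
            c = CLASSES.index(row.template_class)
            lfc = config.template_log2fc * scale[row.template_class]
            tpl[i, c] = lfc if row.template_direction == "up" else -lfc
        elif row.category == "superclass":
            sgn = 1.0 if row.template_direction == "up" else -1.0
            # up (or down) in the canonical superclass {CMS2, CMS4}
            tpl[i, 1] = sgn * config.superclass_log2fc
            tpl[i, 3] = sgn * config.superclass_log2fc
    return tpl


def simulate_cohort(config: SimulationConfig) -> Tuple[ExpressionMatrix, pd.DataFrame, TruthTables]:
    """Draw a full multiregional cohort from the generative model."""
    config = config.validate()
    rng = np.random.default_rng(config.seed)

    genes = _assign_gene_categories(config)
    n_genes = len(genes)
    mu = rng.normal(config.baseline_mean, config.baseline_mean_sd, size=n_genes)

    sizes = np.array(sorted(config.samples_per_tumor))
    probs = np.array([config.samples_per_tumor[s] for s in sizes])
    n_samples_per_tumor = rng.choice(sizes, size=config.n_tumors, p=probs)

    major_idx = rng.choice(4, size=config.n_tumors, p=np.asarray(config.subtype_proportions))
    het = rng.random(config.n_tumors) < config.het_fraction

    tumor_rows, sample_rows = [], []
    weights = []  # per sample, 4-vector of class weights
    tumor_of_sample = []
    for t in range(config.n_tumors):
        tumor_id = f"T{t:03d}"
        patient_id = f"P{t:03d}"
        n = int(n_samples_per_tumor[t])
        major = CLASSES[major_idx[t]]
        minor = config.minor_pairing[major] if het[t] else None
        msi = rng.random() < config.msi_prob_by_class[major_idx[t]]
        tumor_rows.append(
            dict(
                tumor_id=tumor_id,
                patient_id=patient_id,
                major_class=major,
                minor_class=minor,
                heterogeneous=bool(het[t]),
                msi=bool(msi),
                n_samples=n,
            )
        )
        if het[t] and n >= 2:
            n_minor = max(1, int(round(config.minor_sample_fraction * n)))
            n_minor = min(n_minor, n - 1)  # major stays the >=50% component
        else:
            n_minor = 0
        assigned = [minor] * n_minor + [major] * (n - n_minor)
        rng.shuffle(assigned)
        for r, cls in enumerate(assigned, start=1):
            w = np.zeros(4)
            if het[t]:
                other = minor if cls == major else major
                w[CLASSES.index(cls)] = 1.0 - config.admixture
                w[CLASSES.index(other)] = config.admixture
            else:
                w[CLASSES.index(cls)] = 1.0
            sid = f"{tumor_id}_t{r}"
            sample_rows.append(
                dict(
                    sample_id=sid,
                    tumor_id=tumor_id,
                    patient_id=patient_id,
                    site="primary",
                    region_label=f"t{r}",
                    assigned_class=cls,
                    msi_status="MSI" if msi else "MSS",
                )
            )
            weights.append(w)
            tumor_of_sample.append(t)

    weights = np.array(weights)  # n_samples x 4
    tumor_of_sample = np.array(tumor_of_sample)
    n_samples = len(sample_rows)

    tpl = _template_effect_matrix(genes, config)  # n_genes x 4
    effects = tpl @ weights.T  # n_genes x n_samples

    infil = rng.uniform(0.0, 1.0, size=n_samples)
    stromal_scale = np.where(genes["stromal"].to_numpy(), config.stromal_effect_scale, 0.0)
    effects = effects + np.outer(stromal_scale, infil)

    st = genes["sigma_tumor_sq"].to_numpy()
    se = genes["sigma_resid_sq"].to_numpy()
    u = rng.normal(0.0, 1.0, size=(n_genes, config.n_tumors)) * np.sqrt(st)[:, None]
    e = rng.normal(0.0, 1.0, size=(n_genes, n_samples)) * np.sqrt(se)[:, None]

    values = mu[:, None] + effects + u[:, tumor_of_sample] + e

    samples_df = pd.DataFrame(sample_rows)
    for j, c in enumerate(CLASSES):
        samples_df[f"weight_{c}"] = weights[:, j]
    samples_df["infiltration"] = infil

    tumors_df = pd.DataFrame(tumor_rows)

    # --- survival (one patient per tumor) ---
    sm = config.survival
    log_hr = np.array(
        [sm.subtype_log_hr[major_idx[t]] + sm.heterogeneity_log_hr * het[t] for t in range(config.n_tumors)]
    )
    hazard = sm.baseline_hazard * np.exp(log_hr)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = np.minimum(rng.exponential(1.0 / sm.censoring_rate), sm.admin_censor_months)
    time = np.maximum(np.minimum(t_event, t_cens), 1e-3)
    event = t_event <= t_cens
    patients_df = pd.DataFrame(
        dict(
            patient_id=tumors_df["patient_id"],
            true_log_hazard=np.log(hazard),
            time_months=time,
            event=event,
        )
    )

    stage = rng.choice(["I", "II", "III"], size=config.n_tumors, p=[0.25, 0.45, 0.30])
    tumors_df["stage"] = stage

    sheet = samples_df[
        ["sample_id", "tumor_id", "patient_id", "site", "region_label", "msi_status"]
    ].copy()
    sheet["subtype"] = samples_df["assigned_class"]
    per_tumor = tumors_df.set_index("tumor_id")
    sheet["stage"] = sheet["tumor_id"].map(per_tumor["stage"])
    per_patient = patients_df.set_index("patient_id")
    sheet["time_months"] = sheet["patient_id"].map(per_patient["time_months"])
    sheet["event"] = sheet["patient_id"].map(per_patient["event"])
    sheet["endpoint"] = "RFS"

    expr = ExpressionMatrix(
        tuple(genes["gene_id"]), tuple(samples_df["sample_id"]), values
    )
    truth = TruthTables(genes=genes, tumors=tumors_df, samples=samples_df, patients=patients_df)
    return expr, validate_sample_sheet(sheet), truth


def simulate_metastasis_pairs(
    config: SimulationConfig,
    switch_prob: float,
    n_pairs: Optional[int] = None,
    seed: Optional[int] = None,
) -> Tuple[ExpressionMatrix, pd.DataFrame, TruthTables]:
    """Extend a cohort with patient-matched liver-metastasis samples.

    For ``n_pairs`` patients (default: all), one metastasis sample is
    added whose subtype equals the primary tumor's major class with
    probability ``1 - switch_prob`` and is otherwise drawn uniformly from
    the remaining classes (phenotypic plasticity). The metastasis is a
    homogeneous lesion with its own tumor-level random effect.
    """
    if not 0.0 <= switch_prob <= 1.0:
        raise ValueError("switch_prob must be in [0, 1]")
    config = config.validate()
    expr, sheet, truth = simulate_cohort(config)
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)

    patients = list(truth.tumors["patient_id"])
    if n_pairs is not None:
        patients = list(rng.choice(patients, size=min(n_pairs, len(patients)), replace=False))

    genes = truth.genes
    n_genes = len(genes)
    # metastasis values share gene baselines estimated from the primary data
    base = expr.values.mean(axis=1)

    tpl = _template_effect_matrix(genes, config)
    st = genes["sigma_tumor_sq"].to_numpy()
    se = genes["sigma_resid_sq"].to_numpy()
    stromal_scale = np.where(genes["stromal"].to_numpy(), config.stromal_effect_scale, 0.0)

    per_patient_major = truth.tumors.set_index("patient_id")["major_class"]
    new_cols, new_rows, pair_rows = [], [], []
    for p in patients:
        primary_cls = per_patient_major[p]
        if rng.random() < switch_prob:
            choices = [c for c in CLASSES if c != primary_cls]
            met_cls = choices[rng.integers(len(choices))]
        else:
            met_cls = primary_cls
        w = np.zeros(4)
        w[CLASSES.index(met_cls)] = 1.0
        infil = rng.uniform()
        vals = (
            base
            + tpl @ w
            + stromal_scale * infil
            + rng.normal(0.0, 1.0, n_genes) * np.sqrt(st)
            + rng.normal(0.0, 1.0, n_genes) * np.sqrt(se)
        )
        sid = f"{p}_M_T1"
        new_cols.append(vals)
        new_rows.append(
            dict(
                sample_id=sid,
                tumor_id=f"{p}_M",
                patient_id=p,
                site="metastasis",
                region_label="T1",
                msi_status=None,
                subtype=met_cls,
                stage=None,
                time_months=np.nan,
                event=np.nan,
                endpoint=None,
            )
        )
        pair_rows.append(
            dict(
                patient_id=p,
                primary_class=primary_cls,
                metastasis_class=met_cls,
                concordant=met_cls == primary_cls,
            )
        )

    all_values = np.column_stack([expr.values] + [np.asarray(c) for c in new_cols])
    all_ids = list(expr.sample_ids) + [r["sample_id"] for r in new_rows]
    ext_expr = ExpressionMatrix(expr.gene_ids, tuple(all_ids), all_values)
    ext_sheet = pd.concat([sheet, pd.DataFrame(new_rows)], ignore_index=True)
    truth.metastasis_pairs = pd.DataFrame(pair_rows)
    return ext_expr, ext_sheet, truth


def truth_gene_ids(truth: TruthTables, level: str) -> list:
    """Gene ids whose planted variance structure is ITH-low or ITH-high.

    ``level='low'`` returns template, superclass and low-variance
    background genes (between-tumor signal dominates); ``level='high'``
    returns stromal and high-residual background genes.
    """
    cats = {
        "low": {"template", "superclass", "background_low"},
        "high": {"stromal", "background_high"},
        "intermediate": {"background_intermediate"},
    }[level]
    g = truth.genes
    return list(g.loc[g["category"].isin(cats), "gene_id"])
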