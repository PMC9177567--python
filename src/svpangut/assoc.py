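"""SV-stratified bacteria-metabolite-phenotype association cascade.

The cascade mirrors how strain-level structure is dissected in
gut-microbiome cohorts:

1. occurrence filters — species present in >= 50% of samples; SV-affected
   gene (KO) columns with both genotype groups at >= 20% of that species'
   present-samples; metabolites non-missing in > 90% of samples;
2. Spearman screening of (species, metabolite-or-phenotype) pairs over the
   samples where the species is present, with Benjamini-Hochberg FDR control
   per target block (screen threshold q < 0.1);
3. SV dissection of screen-significant pairs: split the present-samples by
   the KO genotype into the SV-absent (SV0) and SV-carrying (SV1) strains; a
   pair is *confounded* by the SV when the SV0 subgroup remains significant
   (p < 0.05) while the SV1 subgroup's correlation is abolished (p > 0.05);
4. optional covariate-controlled post-hoc (partial Spearman on age/sex/BMI).

Samples where a species is absent (abundance 0, genotype NA) are excluded
from that species' correlations; abundances are used as given, since
Spearman is rank-based.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthio import CohortBundle


class EmptyCohortError(RuntimeError):
    """No species survived the occurrence filter."""


# ---------------------------------------------------------------------------
# statistical kernels


def spearman(x, y, exact_max_n: int = 9) -> tuple[float, float]:
    """Midrank Spearman correlation with pairwise-complete handling.

    p comes from the t-distribution approximation, except for n <=
    ``exact_max_n`` where the full permutation distribution of the rank
    correlation is enumerated.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("spearman needs at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("zero variance; Spearman rho undefined")
        return (float("nan"), float("nan"))
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    if n <= exact_max_n:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        rxc = rx - rx.mean()
        denom_x = np.sqrt((rxc**2).sum())
        perms = np.array(list(itertools.permutations(ry)))
        pc = perms - perms.mean(axis=1, keepdims=True)
        denom_y = np.sqrt((pc**2).sum(axis=1))
        rho_perm = (pc @ rxc) / (denom_x * denom_y)
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
    else:
        p = float(res.pvalue)
    return (rho, p)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1);
    NaNs are excluded from the family and propagated."""
    p = np.asarray(pvals, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0,1]")
    q = np.full_like(p, np.nan)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def partial_spearman(x, y, covariates) -> tuple[float, float]:
    """Rank-based partial correlation controlling for covariates.

    Midranks of x and y are residualised on the covariates (with intercept)
    by least squares; Pearson on the residuals, p from t with n - c - 2
    degrees of freedom.  Collinear covariate columns are dropped with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(covariates, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    ok = ~(np.isnan(x) | np.isnan(y) | np.isnan(z).any(axis=1))
    x, y, z = x[ok], y[ok], z[ok]
    n = x.size
    # drop columns that add nothing beyond the intercept / earlier columns
    design = np.ones((n, 1))
    dropped = 0
    for jcol in range(z.shape[1]):
        cand = np.hstack([design, z[:, [jcol]]])
        if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(design):
            design = cand
        else:
            dropped += 1
    if dropped:
        warnings.warn(f"dropped {dropped} collinear covariate column(s)")
    c = design.shape[1] - 1
    if n < c + 3:
        raise ValueError("need n >= c + 3 samples")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    res_x = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    res_y = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    sx, sy = np.sqrt((res_x**2).sum()), np.sqrt((res_y**2).sum())
    if sx == 0 or sy == 0:
        warnings.warn("zero residual variance; partial rho undefined")
        return (float("nan"), float("nan"))
    rho = float(res_x @ res_y / (sx * sy))
    df = n - c - 2
    if abs(rho) >= 1.0:
        return (rho, 0.0)
    t = rho * np.sqrt(df / (1.0 - rho * rho))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return (rho, p)


# ---------------------------------------------------------------------------
# filtering


@dataclass
class FilteredCohort:
    abundance: pd.DataFrame
    sv_genotype: pd.DataFrame
    metabolites: pd.DataFrame
    phenotype: pd.Series
    covariates: pd.DataFrame
    filter_log: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def species(self) -> list[str]:
        return list(self.abundance.columns)

    def sv_columns_for(self, species: str) -> list[str]:
        return [c for c in self.sv_genotype.columns if c.split(":", 1)[0] == species]


def filter_cohort(
    bundle: CohortBundle,
    species_min_occ: float = 0.5,
    sv_group_min: float = 0.2,
    metabolite_min_presence: float = 0.9,
) -> FilteredCohort:
    """Apply the three occurrence filters in order (species, then SV columns
    of retained species, then metabolites) and log every decision."""
    log_rows = []

    occ = (bundle.abundance > 0).mean()
    keep_species = []
    for sp, frac in occ.items():
        kept = frac >= species_min_occ
        log_rows.append({"feature": sp, "rule": "species_min_occ", "value": float(frac), "kept": kept})
        if kept:
            keep_species.append(sp)
    if not keep_species:
        raise EmptyCohortError("no species passes the occurrence filter")

    keep_sv = []
    for col in bundle.sv_genotype.columns:
        sp = col.split(":", 1)[0]
        if sp not in keep_species:
            log_rows.append({"feature": col, "rule": "species_dropped", "value": np.nan, "kept": False})
            continue
        present = bundle.abundance[sp] > 0
        g = bundle.sv_genotype.loc[present, col]
        frac_sv = float((g == 1).mean()) if len(g) else 0.0
        minority = min(frac_sv, 1.0 - frac_sv)
        kept = minority >= sv_group_min
        log_rows.append({"feature": col, "rule": "sv_group_min", "value": minority, "kept": kept})
        if kept:
            keep_sv.append(col)

    keep_met = []
    for met in bundle.metabolites.columns:
        frac = float(bundle.metabolites[met].notna().mean())
        kept = frac > metabolite_min_presence
        log_rows.append({"feature": met, "rule": "metabolite_min_presence", "value": frac, "kept": kept})
        if kept:
            keep_met.append(met)

    return FilteredCohort(
        abundance=bundle.abundance[keep_species],
        sv_genotype=bundle.sv_genotype[keep_sv],
        metabolites=bundle.metabolites[keep_met],
        phenotype=bundle.phenotype,
        covariates=bundle.covariates,
        filter_log=pd.DataFrame(log_rows, columns=["feature", "rule", "value", "kept"]),
    )


# ---------------------------------------------------------------------------
# screen + dissection

_RECORD_COLUMNS = [
    "species", "target", "ko",
    "n_all", "rho_all", "p_all", "q_all",
    "n_sv0", "rho_sv0", "p_sv0",
    "n_sv1", "rho_sv1", "p_sv1",
    "verdict",
]


def _target_frame(fc: FilteredCohort, target_block: str) -> pd.DataFrame:
    if target_block == "metabolites":
        return fc.metabolites
    if target_block == "phenotype":
        return fc.phenotype.to_frame(name=fc.phenotype.name or "phenotype")
    raise ValueError("target_block must be 'metabolites' or 'phenotype'")


def screen_pairs(
    fc: FilteredCohort,
    target_block: str = "metabolites",
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Spearman screen of every (species, target) pair over the species'
    present-samples; BH across all pairs of the target block."""
    targets = _target_frame(fc, target_block)
    rows = []
    for sp in fc.species:
        present = fc.abundance[sp] > 0
        for tgt in targets.columns:
            mask = present & targets[tgt].notna()
            n = int(mask.sum())
            if n < 3:
                rho, p = float("nan"), float("nan")
            else:
                rho, p = spearman(fc.abundance.loc[mask, sp], targets.loc[mask, tgt])
            rows.append(
                {"species": sp, "target": tgt, "ko": None, "n_all": n,
                 "rho_all": rho, "p_all": p, "verdict": "screen_only"}
            )
    df = pd.DataFrame(rows)
    df["q_all"] = bh_adjust(df["p_all"]) if len(df) else []
    df["significant"] = df["q_all"] < fdr
    for col in ("n_sv0", "rho_sv0", "p_sv0", "n_sv1", "rho_sv1", "p_sv1"):
        df[col] = np.nan
    return df[_RECORD_COLUMNS + ["significant"]]


def dissect_by_sv(
    fc: FilteredCohort,
    screen: pd.DataFrame,
    target_block: str = "metabolites",
    alpha_keep: float = 0.05,
    alpha_abolish: float = 0.05,
    fdr: float = 0.1,
) -> pd.DataFrame:
    """For every screen-significant pair, test each retained KO column of the
    species in the SV0 and SV1 subgroups separately.

    verdict is *confounded* iff the SV0 subgroup stays significant
    (p_sv0 < alpha_keep) while the SV1 subgroup is abolished
    (p_sv1 > alpha_abolish); subgroup p-values are reported raw, not
    re-adjusted.
    """
    targets = _target_frame(fc, target_block)
    rows = []
    hits = screen[screen["q_all"] < fdr]
    for _, rec in hits.iterrows():
        sp, tgt = rec["species"], rec["target"]
        present = fc.abundance[sp] > 0
        tmask = present & targets[tgt].notna()
        for col in fc.sv_columns_for(sp):
            g = fc.sv_genotype[col]
            out = {
                "species": sp, "target": tgt, "ko": col.split(":", 1)[1],
                "n_all": rec["n_all"], "rho_all": rec["rho_all"],
                "p_all": rec["p_all"], "q_all": rec["q_all"],
            }
            sub = {}
            for label, want in (("sv0", 0.0), ("sv1", 1.0)):
                mask = tmask & (g == want)
                n = int(mask.sum())
                if n < 3:
                    sub[label] = (n, float("nan"), float("nan"))
                else:
                    rho, p = spearman(fc.abundance.loc[mask, sp], targets.loc[mask, tgt])
                    sub[label] = (n, rho, p)
            (out["n_sv0"], out["rho_sv0"], out["p_sv0"]) = sub["sv0"]
            (out["n_sv1"], out["rho_sv1"], out["p_sv1"]) = sub["sv1"]
            confounded = (
                not np.isnan(out["p_sv0"])
                and not np.isnan(out["p_sv1"])
                and out["p_sv0"] < alpha_keep
                and out["p_sv1"] > alpha_abolish
            )
            out["verdict"] = "confounded" if confounded else "not_confounded"
            rows.append(out)
    return pd.DataFrame(rows, columns=_RECORD_COLUMNS)


def run_cascade(
    bundle: CohortBundle,
    target_block: str = "metabolites",
    species_min_occ: float = 0.5,
    sv_group_min: float = 0.2,
    metabolite_min_presence: float = 0.9,
    fdr: float = 0.1,
    alpha_keep: float = 0.05,
    alpha_abolish: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """filter -> screen -> dissect; returns (screen, dissection, filter_log)."""
    fc = filter_cohort(
        bundle,
        species_min_occ=species_min_occ,
        sv_group_min=sv_group_min,
        metabolite_min_presence=metabolite_min_presence,
    )
    screen = screen_pairs(fc, target_block=target_block, fdr=fdr)
    dissection = dissect_by_sv(
        fc, screen, target_block=target_block,
        alpha_keep=alpha_keep, alpha_abolish=alpha_abolish, fdr=fdr,
    )
    return screen, dissection, fc.filter_log
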