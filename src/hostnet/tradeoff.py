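"""Diet-breadth-dependent performance tests.

Two generalized linear models relate a species' local diet breadth (count
of host taxa used at a taxonomic level) to its performance:

* abundance — number of establishment-stage individuals per colonized
  tree, Poisson with log link, one record per (species, colonized tree);
* occupancy — trees colonized out of trees surveyed within each host
  taxon, binomial with logit link, one record per observed (species,
  taxon) association, excluding taxa with fewer than three surveyed trees.

Significance is permutation-based: the species-level diet-breadth
predictor is shuffled across species and propagated to records; the
empirical slope is Z-tested against the null slopes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datamodel import LinkTable, TestReport, ValidationError, level_column
from .stats import z_test

FAMILIES = ("poisson-log", "binomial-logit")


@dataclass
class AbundanceRecord:
    insect_species: str
    tree_id: str
    host_taxon: str
    response: int  # establishment-stage individuals on the tree, >= 1
    predictor: int  # diet breadth of the species at the chosen level


@dataclass
class OccupancyRecord:
    insect_species: str
    host_taxon: str
    trees_colonized: int
    trees_surveyed: int
    predictor: int


@dataclass
class GlmFit:
    family: str
    intercept: float
    slope: float
    converged: bool
    iterations: int


def diet_breadth(
    lt: LinkTable, level: str, assignment: dict[str, str] | None = None
) -> dict[str, int]:
    """Distinct host taxa (at ``level``) with >= 1 colonized tree, per
    insect species. Equals the row sums of the host-use matrix."""
    links = lt.colonization_links(level)
    if assignment is not None:
        links = links.assign(insect_species=links["insect_species"].map(assignment))
    return (
        links.groupby("insect_species")["host_taxon"].nunique().to_dict()
    )


def build_abundance_records(lt: LinkTable, level: str) -> list[AbundanceRecord]:
    """One record per (species, colonized tree): summed establishment
    counts as the Poisson response, the species' diet breadth as the
    predictor. Uncolonized trees contribute nothing."""
    links = lt.colonization_links(level)
    breadth = diet_breadth(lt, level)
    out = []
    for row in links.itertuples(index=False):
        out.append(
            AbundanceRecord(
                insect_species=row.insect_species,
                tree_id=row.tree_id,
                host_taxon=row.host_taxon,
                response=int(row.abundance),
                predictor=breadth[row.insect_species],
            )
        )
    return out


def build_occupancy_records(
    lt: LinkTable,
    census: pd.DataFrame,
    level: str,
    min_trees: int = 3,
) -> list[OccupancyRecord]:
    """One record per observed (species, host taxon) association.

    ``census`` lists every surveyed tree with its taxonomy (columns
    tree_id, host_species, host_genus, host_family) — the link table alone
    cannot supply surveyed-but-uncolonized trees. Host taxa with fewer
    than ``min_trees`` surveyed trees are excluded.
    """
    col = level_column(level)
    if col not in census.columns or "tree_id" not in census.columns:
        raise ValidationError(f"census must have tree_id and {col} columns")
    surveyed = census.groupby(col)["tree_id"].nunique()
    links = lt.colonization_links(level)
    breadth = diet_breadth(lt, level)
    missing = sorted(set(links["host_taxon"]) - set(surveyed.index))
    if missing:
        raise ValidationError(f"host taxa absent from census: {missing}")
    grouped = links.groupby(["insect_species", "host_taxon"])["tree_id"].nunique()
    out = []
    for (sp, taxon), n_col in grouped.items():
        n_sur = int(surveyed[taxon])
        if n_sur < min_trees:
            continue
        out.append(
            OccupancyRecord(
                insect_species=sp,
                host_taxon=taxon,
                trees_colonized=int(n_col),
                trees_surveyed=n_sur,
                predictor=breadth[sp],
            )
        )
    return out


def _design(records, family: str):
    x = np.array([r.predictor for r in records], dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    if family == "poisson-log":
        y = np.array([r.response for r in records], dtype=float)
        return y, X
    y = np.array(
        [[r.trees_colonized, r.trees_surveyed - r.trees_colonized] for r in records],
        dtype=float,
    )
    return y, X


def fit_glm(records, family: str, intercept_only: bool = False) -> GlmFit:
    """Fit the slope of performance on diet breadth by IRLS.

    Poisson/log for abundance records, binomial/logit for occupancy
    records; convergence at relative deviance change < 1e-10 within 50
    iterations. Non-convergence is flagged, not raised.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    if len(records) < 2:
        raise ValidationError("need at least two records to fit a GLM")
    y, X = _design(records, family)
    if intercept_only:
        X = X[:, :1]
    elif np.ptp(X[:, 1]) == 0:
        raise ValidationError("constant predictor: slope is not estimable")
    fam = sm.families.Poisson() if family == "poisson-log" else sm.families.Binomial()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=fam)
        res = model.fit(maxiter=50, tol=1e-10)
    params = np.asarray(res.params, dtype=float)
    converged = bool(getattr(res, "converged", True)) and np.isfinite(params).all()
    return GlmFit(
        family=family,
        intercept=float(params[0]),
        slope=float(params[1]) if params.size > 1 else 0.0,
        converged=converged,
        iterations=int(getattr(res, "fit_history", {}).get("iteration", 0) or 0),
    )


def _permute_predictor(records, perm_breadth: dict[str, int]):
    out = []
    for r in records:
        r2 = type(r)(**{**vars(r)})
        r2.predictor = perm_breadth[r.insect_species]
        out.append(r2)
    return out


def permutation_significance(
    records,
    family: str,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    max_failed_frac: float = 0.10,
) -> TestReport:
    """Z test of the empirical GLM slope against permutation-null slopes.

    The species-level diet-breadth predictor is shuffled across species
    (the exchangeable unit) and propagated to records before each refit.
    Permutation conserves the multiset of responses and, at species level,
    of predictors. Errors if the empirical fit, or more than 10% of null
    fits, fail to converge.
    """
    rng = np.random.default_rng(rng)
    emp = fit_glm(records, family)
    if not emp.converged:
        raise ValidationError("empirical GLM fit did not converge")
    species = sorted({r.insect_species for r in records})
    breadth = {s: next(r.predictor for r in records if r.insect_species == s)
               for s in species}
    vals = np.array([breadth[s] for s in species])
    nulls = []
    failed = 0
    for _ in range(n_perm):
        perm = {s: int(v) for s, v in zip(species, vals[rng.permutation(len(vals))])}
        try:
            f = fit_glm(_permute_predictor(records, perm), family)
        except ValidationError:
            failed += 1
            continue
        if f.converged:
            nulls.append(f.slope)
        else:
            failed += 1
    if failed > max_failed_frac * n_perm:
        raise ValidationError(
            f"{failed}/{n_perm} null GLM fits failed; permutation Z unreliable"
        )
    m, s, z, p = z_test(emp.slope, nulls)
    return TestReport(
        context={"family": family, "slope": emp.slope},
        empirical=emp.slope,
        null_mean=m,
        null_sd=s,
        z=z,
        p=p,
        n_null=len(nulls),
    )


def tradeoff_table(
    lt: LinkTable,
    census: pd.DataFrame,
    levels=("species", "genus", "family"),
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    site: str = "",
) -> pd.DataFrame:
    """Abundance and occupancy slope tests at each host-taxonomic level."""
    rng = np.random.default_rng(rng)
    rows = []
    for level in levels:
        ab = build_abundance_records(lt, level)
        occ = build_occupancy_records(lt, census, level)
        r_ab = permutation_significance(ab, "poisson-log", n_perm, rng)
        r_oc = permutation_significance(occ, "binomial-logit", n_perm, rng)
        rows.append(
            {
                "site": site,
                "level": level,
                "abundance_slope": r_ab.empirical,
                "abundance_Z": r_ab.z,
                "abundance_p": r_ab.p,
                "occupancy_slope": r_oc.empirical,
                "occupancy_Z": r_oc.z,
                "occupancy_p": r_oc.p,
            }
        )
    return pd.DataFrame(rows)
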