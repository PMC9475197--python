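"""Regression layer: principal-score models, stepwise selection, MDS.

Ten model designs relate clinical outcomes to shape principal scores
(PS): for each outcome (PSS, CTQTOT) there is a covariates-only model
(age + BDI), a scores-only model, a main-effects model, a model adding
score-by-age and score-by-BDI interactions, and the interaction model
augmented with intracranial volume (ICV).  Main effects use the first 15
scores per structure; interaction terms use the first 5 per structure.
Fits are ordinary least squares (statsmodels) with adjusted R^2 and
two-sided t-test p-values; predictor selection is bidirectional stepwise
search on AIC.

Also included: pairwise surface distance matrices (raw L2 or elastic)
and classical (Torgerson) multidimensional scaling with an exact
2-medoid partitioner for the registration diagnostics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .sphere_grid import GridSurface, norm_l2
from .srnf_registration import RegistrationConfig, register_pair

__all__ = [
    "ModelSpec",
    "RegressionFit",
    "DistanceMatrix",
    "model_table",
    "build_design",
    "fit_ols",
    "stepwise_select",
    "pairwise_distance_matrix",
    "classical_mds",
    "two_medoids",
    "clustering_accuracy",
    "registration_triptych",
]

N_MAIN_SCORES = 15
N_INTERACTION_SCORES = 5


@dataclass
class ModelSpec:
    """One of the ten model designs.

    ``terms`` is the predictor recipe: "age", "BDI", "ICV", "PS"
    (main-effect scores), "PSxage"/"PSxBDI" (interaction blocks).
    """

    model_no: int
    outcome: str
    terms: tuple


def model_table() -> dict:
    """The ten standard designs, keyed by model number."""
    full = ("age", "BDI", "PS", "PSxage", "PSxBDI")
    return {
        1: ModelSpec(1, "PSS", full),
        2: ModelSpec(2, "PSS", ("age", "BDI", "PS")),
        3: ModelSpec(3, "PSS", ("age", "BDI")),
        4: ModelSpec(4, "PSS", ("PS",)),
        5: ModelSpec(5, "CTQTOT", full),
        6: ModelSpec(6, "CTQTOT", ("age", "BDI", "PS")),
        7: ModelSpec(7, "CTQTOT", ("age", "BDI")),
        8: ModelSpec(8, "CTQTOT", ("PS",)),
        9: ModelSpec(9, "PSS", full + ("ICV",)),
        10: ModelSpec(10, "CTQTOT", full + ("ICV",)),
    }


@dataclass
class RegressionFit:
    coefficients: pd.Series
    p_values: pd.Series
    adjusted_r2: float
    r2: float
    selected_terms: list
    n: int
    p: int
    model: object = field(repr=False, default=None)


@dataclass
class DistanceMatrix:
    D: np.ndarray
    labels: list

    def __post_init__(self) -> None:
        d = np.asarray(self.D, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        self.D = d


def _score_columns(table: pd.DataFrame, limit: int) -> list:
    """Score columns '<structure>_PS<d>' with d <= limit, grouped by structure."""
    cols: dict[str, list[tuple[int, str]]] = {}
    for c in table.columns:
        if "_PS" not in c:
            continue
        struct, _, idx = c.rpartition("_PS")
        if not idx.isdigit():
            continue
        d = int(idx)
        if d <= limit:
            cols.setdefault(struct, []).append((d, c))
    out = []
    for struct in sorted(cols):
        out.extend(name for _, name in sorted(cols[struct]))
    return out


def build_design(
    table: pd.DataFrame,
    spec: ModelSpec,
    standardize_scores: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Design matrix (with intercept) and outcome vector for one model.

    Interaction columns are elementwise products, e.g. amygdala PC1 x
    age.  Score columns are z-scored before forming products by default,
    which tames interaction collinearity; pass ``standardize_scores=
    False`` for raw-scale scores.
    """
    if spec.outcome not in table.columns:
        raise KeyError(f"outcome column {spec.outcome!r} missing")
    if table.isna().any(axis=None):
        bad = table.index[table.isna().any(axis=1)].tolist()
        raise ValueError(f"NaN rows in clinical table: {bad}")
    y = table[spec.outcome].astype(float)
    design = pd.DataFrame({"intercept": np.ones(len(table))}, index=table.index)

    def score_frame(limit):
        cols = _score_columns(table, limit)
        block = table[cols].astype(float)
        if standardize_scores:
            sd = block.std(ddof=0).replace(0.0, 1.0)
            block = (block - block.mean()) / sd
        return block

    for term in spec.terms:
        if term in ("age", "BDI", "ICV"):
            if term not in table.columns:
                raise KeyError(f"column {term!r} missing from table")
            design[term] = table[term].astype(float)
        elif term == "PS":
            design = pd.concat([design, score_frame(N_MAIN_SCORES)], axis=1)
        elif term in ("PSxage", "PSxBDI"):
            moderator = "age" if term == "PSxage" else "BDI"
            block = score_frame(N_INTERACTION_SCORES)
            prods = block.mul(table[moderator].astype(float), axis=0)
            prods.columns = [f"{c}.x.{moderator}" for c in block.columns]
            design = pd.concat([design, prods], axis=1)
        else:
            raise KeyError(f"unknown design term {term!r}")
    return design, y


def fit_ols(
    design: pd.DataFrame, outcome: pd.Series, bh_adjust: bool = False
) -> RegressionFit:
    """OLS fit with adjusted R^2 and per-term two-sided p-values.

    Aliased (perfectly collinear) columns are dropped with a warning
    before fitting.  ``bh_adjust=True`` applies Benjamini-Hochberg FDR
    adjustment to the non-intercept p-values (off by default; the
    standard reports are unadjusted).
    """
    x = design.copy()
    # drop aliased columns by rank-revealing QR on the centered design
    if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
        import warnings

        keep = []
        for c in x.columns:
            trial = x[keep + [c]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(c)
        dropped = [c for c in x.columns if c not in keep]
        warnings.warn(f"dropping aliased design columns: {dropped}")
        x = x[keep]
    n, p_with_intercept = x.shape
    p = p_with_intercept - (1 if "intercept" in x.columns else 0)
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    res = sm.OLS(outcome, x).fit()
    r2 = float(res.rsquared)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    p_values = res.pvalues
    if bh_adjust:
        from statsmodels.stats.multitest import multipletests

        mask = p_values.index != "intercept"
        if mask.any():
            adj_p = multipletests(p_values[mask].to_numpy(), method="fdr_bh")[1]
            p_values = p_values.copy()
            p_values[mask] = adj_p
    return RegressionFit(
        coefficients=res.params,
        p_values=p_values,
        adjusted_r2=float(adj),
        r2=r2,
        selected_terms=[c for c in x.columns if c != "intercept"],
        n=n,
        p=p,
        model=res,
    )


def stepwise_select(
    design: pd.DataFrame,
    outcome: pd.Series,
    criterion: str = "aic",
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_steps: int = 200,
) -> RegressionFit:
    """Bidirectional stepwise predictor selection.

    Starting from the intercept-only model, each step considers adding
    the candidate that most improves the criterion and dropping the
    included term whose removal most improves it, taking the better of
    the two; the search stops when neither move improves.  Deterministic
    given the inputs.  ``criterion`` is "aic" (default) or "pvalue"
    (classic enter/remove thresholds).
    """
    candidates = [c for c in design.columns if c != "intercept"]
    included: list[str] = []

    def fit_subset(terms):
        cols = ["intercept"] + list(terms) if "intercept" in design.columns else list(terms)
        return sm.OLS(outcome, design[cols]).fit()

    if criterion == "aic":
        current = fit_subset(included)
        score = current.aic
        for _ in range(max_steps):
            moves = []
            for c in candidates:
                if c not in included:
                    m = fit_subset(included + [c])
                    moves.append((m.aic, "add", c))
            for c in included:
                m = fit_subset([t for t in included if t != c])
                moves.append((m.aic, "drop", c))
            if not moves:
                break
            moves.sort(key=lambda t: (t[0], t[1], t[2]))
            best_score, action, term = moves[0]
            if best_score >= score - 1e-9:
                break
            score = best_score
            if action == "add":
                included.append(term)
            else:
                included.remove(term)
    elif criterion == "pvalue":
        for _ in range(max_steps):
            changed = False
            best = (1.0, None)
            for c in candidates:
                if c in included:
                    continue
                m = fit_subset(included + [c])
                pv = m.pvalues.get(c, 1.0)
                if pv < best[0]:
                    best = (pv, c)
            if best[1] is not None and best[0] < p_enter:
                included.append(best[1])
                changed = True
            if included:
                m = fit_subset(included)
                worst = m.pvalues.drop("intercept", errors="ignore").idxmax()
                if m.pvalues[worst] > p_remove:
                    included.remove(worst)
                    changed = True
            if not changed:
                break
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    cols = (["intercept"] if "intercept" in design.columns else []) + included
    return fit_ols(design[cols], outcome)


def pairwise_distance_matrix(
    surfaces: list,
    mode: str = "raw-L2",
    config: RegistrationConfig | None = None,
) -> DistanceMatrix:
    """All pairwise surface distances.

    ``raw-L2``: plain L2 norms of surface differences (registration
    ignored).  ``elastic``: the elastic shape distance via full pairwise
    registration, symmetrized by averaging the two directions.
    """
    n = len(surfaces)
    grid = surfaces[0].grid
    for s in surfaces:
        if not s.grid.same_as(grid):
            raise ValueError("surfaces must share one grid")
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        if mode == "raw-L2":
            dij = norm_l2(surfaces[i].f - surfaces[j].f, grid)
        elif mode == "elastic":
            dij = 0.5 * (
                register_pair(surfaces[i], surfaces[j], config=config).distance
                + register_pair(surfaces[j], surfaces[i], config=config).distance
            )
        else:
            raise ValueError(f"unknown mode {mode!r}")
        d[i, j] = d[j, i] = dij
    labels = [s.provenance for s in surfaces]
    return DistanceMatrix(D=d, labels=labels)


def classical_mds(dist: DistanceMatrix, dim: int = 2) -> np.ndarray:
    """Torgerson classical MDS: double-center -1/2 D^2, eigen-embed.

    Returns an (n, dim) mean-centered embedding; if fewer than ``dim``
    positive eigenvalues exist the embedding is truncated with a warning.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    d2 = dist.D**2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-12 * max(evals[0], 1e-300)
    n_pos = int(pos.sum())
    if n_pos < dim:
        import warnings

        warnings.warn(f"only {n_pos} positive eigenvalues; truncating embedding")
        dim = max(n_pos, 1)
    emb = evecs[:, :dim] * np.sqrt(np.maximum(evals[:dim], 0.0))
    return emb - emb.mean(axis=0)


def clustering_accuracy(pred: np.ndarray, labels: np.ndarray) -> float:
    """Two-class agreement up to label permutation."""
    pred = np.asarray(pred)
    labels = np.asarray(labels)
    agree = float(np.mean(pred == labels))
    return max(agree, 1.0 - agree)


def registration_triptych(
    line,
    amplitude: float = 0.3,
    seed: int = 0,
    config: RegistrationConfig | None = None,
) -> dict:
    """Clustering diagnostics before/after random reparameterization.

    Stage one clusters the raw distance matrix (and its 2-D classical-MDS
    embedding) of an aligned collinear surface family.  Stage two applies
    an independent random sphere diffeomorphism to every surface and
    re-clusters the now parameterization-confounded distances.  Stage
    three elastically registers each perturbed surface to the family mean
    and clusters the distances of the registered surfaces.  Each stage
    reports the two-class accuracy on the distance matrix and on its 2-D
    MDS embedding (plus the 1-D embedding for the restored stage, the
    natural readout for a planted one-dimensional family).
    """
    from scipy.spatial.distance import pdist, squareform

    from .sphere_grid import center_and_scale
    from .synthetic_data import random_diffeomorphism
    from .srnf_registration import apply_reparam

    labels = line.labels

    def accs(d, dims=(2,)):
        out = [clustering_accuracy(two_medoids(d), labels)]
        for dim in dims:
            emb = classical_mds(d, dim)
            d_emb = DistanceMatrix(squareform(pdist(emb)), d.labels)
            out.append(clustering_accuracy(two_medoids(d_emb), labels))
        return out

    d_aligned = pairwise_distance_matrix(line.surfaces, mode="raw-L2")
    acc_aligned, acc_aligned_mds = accs(d_aligned)

    grid = line.mu.grid
    perturbed = []
    for i, s in enumerate(line.surfaces):
        gam = random_diffeomorphism(grid, amplitude=amplitude, seed=seed * 1000 + i)
        perturbed.append(apply_reparam(s, gam))
    d_pert = pairwise_distance_matrix(perturbed, mode="raw-L2")
    acc_pert, acc_pert_mds = accs(d_pert)

    mu = center_and_scale(line.mu)
    restored = [
        register_pair(mu, center_and_scale(p), config=config).registered_surface
        for p in perturbed
    ]
    d_rest = pairwise_distance_matrix(restored, mode="raw-L2")
    acc_rest, acc_rest_mds, acc_rest_mds1 = accs(d_rest, dims=(2, 1))
    return {
        "aligned": acc_aligned,
        "aligned_mds": acc_aligned_mds,
        "perturbed": acc_pert,
        "perturbed_mds": acc_pert_mds,
        "restored": acc_rest,
        "restored_mds": acc_rest_mds,
        "restored_mds1": acc_rest_mds1,
    }


def two_medoids(dist: DistanceMatrix) -> np.ndarray:
    """Exact 2-medoid partition by exhaustive search over medoid pairs.

    Minimizes the total distance of points to their nearer medoid;
    returns 0/1 labels.  Exhaustive search is exact and deterministic
    (n choose 2 candidate pairs).
    """
    d = dist.D
    n = d.shape[0]
    best_cost = np.inf
    best_labels = np.zeros(n, dtype=int)
    for i, j in itertools.combinations(range(n), 2):
        assign = (d[j] < d[i]).astype(int)
        cost = float(np.where(assign == 0, d[i], d[j]).sum())
        if cost < best_cost:
            best_cost = cost
            best_labels = assign
    return best_labels
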