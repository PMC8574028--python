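"""Stage (D): module eigengenes and LASSO-based trait association.

Each detected module is summarised by its *eigengene*: the first right
singular vector of the module's gene × genotype LFC submatrix after each
gene row is z-scored.  The eigengene is a per-genotype profile capturing the
module's dominant co-variation pattern; its sign is fixed so that it
correlates non-negatively with the mean standardized row (falling back to
the first gene's row when the mean is numerically zero, e.g. for perfectly
anti-correlated pairs).

Trait association solves, once per trait, the L1-penalized least squares
problem

    minimize  ||y - X a||^2 + lambda * ||a||_1

over module coefficients a, where the columns of X are eigengenes
(standardized) and y is the trait's log2 phenotype ratio across genotypes
(centered).  The penalty drives coefficients of irrelevant modules exactly
to zero, so the surviving modules are the trait-associated ones.  lambda is
chosen by k-fold cross-validation as the grid value minimizing the mean
held-out squared error.  The KKT conditions of the objective are
|x_j'(y - Xa)| <= lambda/2 for inactive coefficients, with equality at
lambda/2 (signed) for active ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import LfcMatrix, PhenoLfcTable
from .hlc import AffiliationMatrix


@dataclass(frozen=True)
class EigengeneMatrix:
    genotype_ids: list[str]
    module_ids: list[str]
    values: np.ndarray  # genotypes × modules, unit-norm columns

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.genotype_ids), len(self.module_ids)):
            raise ValueError("eigengene matrix shape mismatch")
        if v.size:
            norms = np.linalg.norm(v, axis=0)
            if not np.allclose(norms, 1.0):
                raise ValueError("eigengene columns must be unit-norm")


@dataclass(frozen=True)
class LassoFit:
    trait_name: str
    lambda_grid: np.ndarray
    cv_mse_mean: np.ndarray
    cv_mse_se: np.ndarray
    chosen_lambda: float
    coefficients: np.ndarray  # per module, standardized-predictor scale
    intercept: float
    module_ids: list[str]
    fold_seed: int

    def active_modules(self) -> list[str]:
        return [m for m, a in zip(self.module_ids, self.coefficients) if a != 0.0]


@dataclass(frozen=True)
class SelectionResult:
    """Per-trait selected modules W_z and the gene union I with attribution."""

    modules_per_trait: dict[str, list[str]]
    coefficients_per_trait: dict[str, dict[str, float]]
    lambda_per_trait: dict[str, float]
    gene_traits: dict[str, list[str]]  # gene -> traits it is attributed to
    gene_modules: dict[str, list[str]]  # gene -> selected modules containing it

    @property
    def selected_genes(self) -> list[str]:
        return sorted(self.gene_traits)

    def to_dict(self) -> dict:
        return {
            "traits": {
                t: {
                    "lambda": self.lambda_per_trait[t],
                    "modules": self.modules_per_trait[t],
                    "coefficients": self.coefficients_per_trait[t],
                }
                for t in self.modules_per_trait
            },
            "genes": {
                g: {"traits": self.gene_traits[g], "modules": self.gene_modules[g]}
                for g in self.selected_genes
            },
        }


def eigengene(l1: LfcMatrix, gene_set: list[str]) -> np.ndarray:
    """First principal profile of a gene set across genotypes.

    Rows of the LFC matrix restricted to ``gene_set`` are z-scored per gene,
    then the first right singular vector of the resulting matrix is returned
    (unit norm, sign fixed as described in the module docstring).
    """
    if not gene_set:
        raise ValueError("gene set must be nonempty")
    rows = l1.rows_for(gene_set)
    sd = rows.std(axis=1)
    if (sd == 0).any():
        bad = gene_set[int(np.argmax(sd == 0))]
        raise ValueError(f"gene {bad!r} has zero variance; cannot z-score for the eigengene")
    z = (rows - rows.mean(axis=1, keepdims=True)) / sd[:, np.newaxis]
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    v = vt[0]
    mean_row = z.mean(axis=0)
    ref = mean_row if np.linalg.norm(mean_row) > 1e-10 else z[0]
    if float(ref @ v) < 0:
        v = -v
    return v / np.linalg.norm(v)


def eigengene_matrix(l1: LfcMatrix, f: AffiliationMatrix) -> EigengeneMatrix:
    """One eigengene column per module, module order preserved."""
    cols = []
    for m in f.module_ids:
        genes = [g for g in f.module_genes[m] if g in set(l1.gene_ids)]
        if not genes:
            raise ValueError(f"module {m!r} has no genes present in the LFC matrix")
        cols.append(eigengene(l1, genes))
    values = np.column_stack(cols) if cols else np.zeros((len(l1.genotype_ids), 0))
    return EigengeneMatrix(
        genotype_ids=list(l1.genotype_ids), module_ids=list(f.module_ids), values=values
    )


def _standardize(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in the regression inputs")
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    if (sd == 0).any():
        j = int(np.argmax(sd == 0))
        raise ValueError(f"predictor column {j} has zero variance")
    xs = (x - mu) / sd
    intercept = float(y.mean())
    return xs, y - intercept, intercept


def _soft(v: float, t: float) -> float:
    if v > t:
        return v - t
    if v < -t:
        return v + t
    return 0.0


def _cd_kernel_py(
    xtx: np.ndarray,
    xty: np.ndarray,
    alpha: np.ndarray,
    half_lam: float,
    stop: float,
    max_iter: int,
) -> np.ndarray:
    c = alpha.shape[0]
    diag = np.diag(xtx).copy()
    q = xtx @ alpha
    for _ in range(max_iter):
        for j in range(c):
            if diag[j] <= 0.0:
                continue
            aj = alpha[j]
            rho = xty[j] - q[j] + diag[j] * aj
            if rho > half_lam:
                new = (rho - half_lam) / diag[j]
            elif rho < -half_lam:
                new = (rho + half_lam) / diag[j]
            else:
                new = 0.0
            if new != aj:
                q += xtx[:, j] * (new - aj)
                alpha[j] = new
        q = xtx @ alpha  # refresh to keep float drift out of the stopping check
        grad = xty - q
        viol = 0.0
        for j in range(c):
            if alpha[j] == 0.0:
                v = abs(grad[j]) - half_lam
            else:
                v = abs(grad[j] - half_lam * (1.0 if alpha[j] > 0 else -1.0))
            if v > viol:
                viol = v
        if viol < stop:
            break
    return alpha


try:  # jit-compile the hot loop when numba is present; semantics are identical
    from numba import njit

    _cd_kernel = njit(cache=True)(_cd_kernel_py)
except Exception:  # pragma: no cover - exercised only without numba
    _cd_kernel = _cd_kernel_py


def coordinate_descent(
    xs: np.ndarray,
    yc: np.ndarray,
    lam: float,
    alpha0: np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 200_000,
    gram: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Cyclic coordinate descent on ||y - Xa||^2 + lam * ||a||_1.

    Inputs are assumed pre-standardized/centered.  Works on the gram matrices
    (X'X, X'y), which may be passed precomputed when solving many penalties on
    the same design.  Stops when the maximum KKT violation — |x_j'(y - Xa)|
    exceeding lam/2 for inactive j, or the signed stationarity residual for
    active j — falls below ``tol`` (scaled by lam/2 when that is larger than
    one).  Deterministic for fixed inputs.
    """
    _, c = xs.shape
    if gram is None:
        xtx = xs.T @ xs
        xty = xs.T @ yc
    else:
        xtx, xty = gram
    alpha = np.zeros(c) if alpha0 is None else np.asarray(alpha0, dtype=float).copy()
    half_lam = lam / 2.0
    scale = max(1.0, float(np.abs(xty).max(initial=0.0)), half_lam)
    return _cd_kernel(
        np.ascontiguousarray(xtx, dtype=np.float64),
        np.ascontiguousarray(xty, dtype=np.float64),
        alpha,
        half_lam,
        tol * scale,
        max_iter,
    )


def fit_lasso(x: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """LASSO coefficients at a fixed penalty.

    Standardizes predictor columns and centers the response internally;
    coefficients are reported on the standardized-predictor scale.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    xs, yc, _ = _standardize(x, y)
    return coordinate_descent(xs, yc, lam)


def lambda_max(x: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which every coefficient is zero: 2 * max_j |x_j' y|
    (on the standardized scale), from the KKT condition of the objective."""
    xs, yc, _ = _standardize(x, y)
    return 2.0 * float(np.abs(xs.T @ yc).max())


def lambda_grid(lam_max: float, n_lambda: int = 100, min_ratio: float = 1e-4) -> np.ndarray:
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def cv_select_lambda(
    x: np.ndarray,
    y: np.ndarray,
    k_folds: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
    rule: str = "1se",
    trait_name: str = "",
    module_ids: list[str] | None = None,
) -> LassoFit:
    """Cross-validated penalty selection plus the final fit.

    Folds come from a seeded permutation of the samples; the lambda grid has
    ``n_lambda`` log-spaced values from lambda_max down to
    ``lambda_min_ratio * lambda_max``.  Coefficient paths are warm-started
    along the grid.  Standardization is done once on the full data so the
    grid is common across folds and the procedure is deterministic.

    ``rule`` chooses the penalty from the CV curve: ``"min"`` takes the grid
    value minimizing the mean held-out MSE; ``"1se"`` (default) takes the
    largest penalty whose mean MSE is within one standard error of that
    minimum — the conventional guard against the mild overselection of the
    plain minimum on small samples.
    """
    if rule not in ("min", "1se"):
        raise ValueError("rule must be 'min' or '1se'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m = x.shape[0]
    if k_folds < 2 or m < k_folds:
        raise ValueError(f"need 2 <= k_folds <= n_samples, got k_folds={k_folds}, n={m}")
    if x.shape[1] == 0:  # no predictors (e.g. no module survived): empty fit
        return LassoFit(
            trait_name=trait_name,
            lambda_grid=np.zeros(0),
            cv_mse_mean=np.zeros(0),
            cv_mse_se=np.zeros(0),
            chosen_lambda=0.0,
            coefficients=np.zeros(0),
            intercept=float(y.mean()),
            module_ids=list(module_ids) if module_ids is not None else [],
            fold_seed=int(seed),
        )
    xs, yc, intercept = _standardize(x, y)
    lam_max = 2.0 * float(np.abs(xs.T @ yc).max())
    if lam_max == 0.0:
        grid = np.zeros(n_lambda)
    else:
        grid = lambda_grid(lam_max, n_lambda, lambda_min_ratio)

    rng = np.random.default_rng(seed)
    order = rng.permutation(m)
    folds = np.array_split(order, k_folds)

    mse = np.zeros((k_folds, len(grid)))
    for f_idx, test_idx in enumerate(folds):
        train_mask = np.ones(m, dtype=bool)
        train_mask[test_idx] = False
        x_tr, y_tr = xs[train_mask], yc[train_mask]
        x_te, y_te = xs[test_idx], yc[test_idx]
        gram = (x_tr.T @ x_tr, x_tr.T @ y_tr)
        alpha = np.zeros(xs.shape[1])
        for l_idx, lam in enumerate(grid):
            # held-out MSE is insensitive to the last digits of alpha, so the
            # CV path runs at a looser tolerance than final fits
            alpha = coordinate_descent(
                x_tr, y_tr, lam, alpha0=alpha, gram=gram, tol=1e-6, max_iter=2000
            )
            resid = y_te - x_te @ alpha
            mse[f_idx, l_idx] = float((resid**2).mean())
    mean_mse = mse.mean(axis=0)
    se_mse = mse.std(axis=0, ddof=1) / np.sqrt(k_folds)
    best = int(np.argmin(mean_mse))  # first (largest lambda) on exact ties
    if rule == "1se":
        ceiling = mean_mse[best] + se_mse[best]
        best = int(np.argmax(mean_mse <= ceiling))  # grid descends from lambda_max
    chosen = float(grid[best])

    # final fit on all data at the chosen penalty, warm-started along the path
    gram_full = (xs.T @ xs, xs.T @ yc)
    alpha = np.zeros(xs.shape[1])
    for lam in grid[: best + 1]:
        alpha = coordinate_descent(xs, yc, lam, alpha0=alpha, gram=gram_full)
    return LassoFit(
        trait_name=trait_name,
        lambda_grid=grid,
        cv_mse_mean=mean_mse,
        cv_mse_se=se_mse,
        chosen_lambda=chosen,
        coefficients=alpha,
        intercept=intercept,
        module_ids=list(module_ids) if module_ids is not None else [],
        fold_seed=int(seed),
    )


def fit_all_traits(
    m: EigengeneMatrix,
    pheno_lfc: PhenoLfcTable,
    k_folds: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
    rule: str = "1se",
) -> list[LassoFit]:
    """One cross-validated LASSO per trait; per-trait seeds derive from ``seed``."""
    if m.genotype_ids != pheno_lfc.genotype_ids:
        raise ValueError("eigengene matrix and phenotype LFC table disagree on genotypes")
    fits = []
    for z, trait in enumerate(pheno_lfc.trait_names):
        fits.append(
            cv_select_lambda(
                m.values,
                pheno_lfc.trait_column(trait),
                k_folds=k_folds,
                seed=(int(seed) + z) % (2**31),
                n_lambda=n_lambda,
                lambda_min_ratio=lambda_min_ratio,
                rule=rule,
                trait_name=trait,
                module_ids=m.module_ids,
            )
        )
    return fits


def select_modules(fits: list[LassoFit], f: AffiliationMatrix) -> SelectionResult:
    """Selected modules per trait and the union gene set with attribution."""
    modules_per_trait: dict[str, list[str]] = {}
    coef_per_trait: dict[str, dict[str, float]] = {}
    lam_per_trait: dict[str, float] = {}
    gene_traits: dict[str, set[str]] = {}
    gene_modules: dict[str, set[str]] = {}
    for fit in fits:
        active = fit.active_modules()
        modules_per_trait[fit.trait_name] = active
        coef_per_trait[fit.trait_name] = {
            mod: float(a)
            for mod, a in zip(fit.module_ids, fit.coefficients)
            if a != 0.0
        }
        lam_per_trait[fit.trait_name] = fit.chosen_lambda
        for mod in active:
            for g in f.module_genes[mod]:
                gene_traits.setdefault(g, set()).add(fit.trait_name)
                gene_modules.setdefault(g, set()).add(mod)
    return SelectionResult(
        modules_per_trait=modules_per_trait,
        coefficients_per_trait=coef_per_trait,
        lambda_per_trait=lam_per_trait,
        gene_traits={g: sorted(ts) for g, ts in gene_traits.items()},
        gene_modules={g: sorted(ms) for g, ms in gene_modules.items()},
    )
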