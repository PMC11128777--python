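"""Full-information maximum likelihood for twin family blocks.

Mean and covariance structures are specified declaratively
(:class:`TwinModelSpec`) and fitted by maximising the sum of per-family
multivariate-normal log densities, each family contributing the density of
its observed cells only (FIML). Variance components use the direct
variance parameterisation: A, C and E enter the expected covariance
linearly and are unbounded, so negative component estimates are possible;
positive definiteness is enforced only softly, by handing the optimizer a
pseudo-infinite objective value whenever an observed submatrix fails a
Cholesky factorisation.

Expected within-family covariance (per trait pair, direct parameters)::

    member-self        A + C + E          (+ D when enabled)
    MZ co-twin         A + C              (+ D)
    DZ co-twin         0.5*A + C          (+ 0.25*D)
    twin - sibling     0.5*A + C          (+ 0.25*D)

Internally, traits and covariates are centred and scaled before
optimisation and estimates are transformed back, so the optimizer always
works near unit scale regardless of the mm^3 magnitudes involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import linalg, optimize, stats

from .cohort import Cohort, FamilyBlock, family_blocks
from .errors import FitError, ValidationError

__all__ = ["TwinModelSpec", "FitResult", "block_loglik", "fit", "lrt", "profile_ci"]

_LOG_2PI = math.log(2.0 * math.pi)
_BIG = 1e12  # soft failure value handed to the optimizer


# ---------------------------------------------------------------------------
# block log-likelihood (reference implementation; the fitter uses a
# pattern-grouped vectorised equivalent, tested against this one)

def block_loglik(y: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float:
    """Log-likelihood contribution of one family block.

    ``y`` is the stacked phenotype vector of the family (NaN = missing);
    ``mu``/``sigma`` are the model-implied mean and covariance for the
    complete block. The density is evaluated for the observed subvector
    under the corresponding row/column subset. A block with no observed
    values contributes exactly 0; a non-positive-definite observed
    submatrix yields ``-inf`` (soft failure), never an exception.
    """
    y = np.asarray(y, dtype=float).ravel()
    mu = np.asarray(mu, dtype=float).ravel()
    sigma = np.asarray(sigma, dtype=float)
    obs = ~np.isnan(y)
    k = int(obs.sum())
    if k == 0:
        return 0.0
    r = y[obs] - mu[obs]
    s = sigma[np.ix_(obs, obs)]
    try:
        L = np.linalg.cholesky(s)
    except np.linalg.LinAlgError:
        return -np.inf
    w = linalg.solve_triangular(L, r, lower=True)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return -0.5 * (k * _LOG_2PI + logdet + float(w @ w))


# ---------------------------------------------------------------------------
# model specification

@dataclass(frozen=True)
class TwinModelSpec:
    """Declarative mean/covariance structure for 1 or 2 traits.

    kind
        ``"variance_components"`` — ACE-family structure with components
        drawn from ``components`` (E always present; optional D behind the
        ``use_d`` flag, never selected by the default pipelines).
        ``"saturated"`` — free means and variances per twin-order x
        zygosity group (plus sibling terms), free per-group co-twin
        covariance; single trait only.
    covariates
        Subset of ("age", "sex", "icv"); coefficients are per dataset
        (and per trait).
    equate_datasets
        When True, variance parameters are shared across datasets
        (mean model stays dataset-specific).
    ties / fixes
        Equality constraints (parameter -> parameter it must equal) and
        point constraints (parameter -> value). All constraint-based
        submodels are expressed this way.
    """

    traits: tuple[str, ...]
    kind: str = "variance_components"
    components: tuple[str, ...] = ("A", "C", "E")
    covariates: tuple[str, ...] = ()
    equate_datasets: bool = True
    ties: dict = field(default_factory=dict)
    fixes: dict = field(default_factory=dict)
    dz_a: float = 0.5
    use_d: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("variance_components", "saturated"):
            raise ValidationError(f"unknown model kind {self.kind!r}")
        if not 1 <= len(self.traits) <= 2:
            raise ValidationError("traits must name 1 or 2 regions")
        if self.kind == "saturated" and len(self.traits) != 1:
            raise ValidationError("saturated structure is univariate only")
        if "E" not in self.components:
            raise ValidationError("E must always be present")
        bad = set(self.components) - {"A", "C", "D", "E"}
        if bad:
            raise ValidationError(f"unknown components: {sorted(bad)}")
        if "D" in self.components and not self.use_d:
            raise ValidationError("D requires use_d=True (non-default structure)")
        bad_cov = set(self.covariates) - {"age", "sex", "icv"}
        if bad_cov:
            raise ValidationError(f"unknown covariates: {sorted(bad_cov)}")

    def with_constraints(self, ties: dict | None = None,
                         fixes: dict | None = None) -> "TwinModelSpec":
        new_ties = dict(self.ties)
        new_ties.update(ties or {})
        new_fixes = dict(self.fixes)
        new_fixes.update(fixes or {})
        return replace(self, ties=new_ties, fixes=new_fixes)

    def drop_components(self, *comps: str) -> "TwinModelSpec":
        """Submodel with the named components fixed to zero (direct
        parameterisation: dropping C means fixing every C parameter at 0)."""
        fixes = {}
        for name_comp in comps:
            fixes[f"__component__{name_comp}"] = 0.0
        return self.with_constraints(fixes=fixes)


@dataclass
class FitResult:
    """Converged (or failed) maximum-likelihood fit."""

    spec: TwinModelSpec
    estimates: dict[str, float]
    minus2LL: float
    n_params: int
    converged: bool
    standardized: dict[str, float]
    diagnostics: dict = field(default_factory=dict)
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    _internal: object = None  # _Prepared + internal theta, for profiling

    @property
    def aic(self) -> float:
        return self.minus2LL + 2.0 * self.n_params

    def to_dict(self) -> dict:
        return {
            "traits": list(self.spec.traits),
            "kind": self.spec.kind,
            "components": list(self.spec.components),
            "estimates": self.estimates,
            "minus2LL": self.minus2LL,
            "n_params": self.n_params,
            "aic": self.aic,
            "converged": self.converged,
            "standardized": self.standardized,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
        }


# ---------------------------------------------------------------------------
# parameter bookkeeping

class _ParamMap:
    """Named parameters with equality ties and point fixes.

    The free vector covers canonical (untied, unfixed) names; ``expand``
    rebuilds the full named vector.
    """

    def __init__(self, names: Sequence[str], ties: dict, fixes: dict):
        self.names = list(names)
        index = {n: i for i, n in enumerate(self.names)}
        unknown = [n for n in list(ties) + list(ties.values()) + list(fixes)
                   if n not in index]
        if unknown:
            raise ValidationError(f"constraints reference unknown parameters: {unknown}")
        canon = {}
        for n in self.names:
            seen = set()
            c = n
            while c in ties:
                if c in seen:
                    raise ValidationError(f"cyclic tie involving {c!r}")
                seen.add(c)
                c = ties[c]
            canon[n] = c
        self.canon = canon
        self.fixes = {canon[k]: float(v) for k, v in fixes.items()}
        self.free_names = [n for n in self.names
                           if canon[n] == n and n not in self.fixes]
        self.free_index = {n: i for i, n in enumerate(self.free_names)}

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def expand(self, theta: np.ndarray) -> dict[str, float]:
        out = {}
        for n in self.names:
            c = self.canon[n]
            out[n] = self.fixes[c] if c in self.fixes else theta[self.free_index[c]]
        return out

    def collapse(self, full: dict[str, float]) -> np.ndarray:
        return np.array([full[n] for n in self.free_names], dtype=float)


# ---------------------------------------------------------------------------
# prepared model: pattern-grouped data + structure builders

def _zyg_class(zyg: str | None) -> str:
    if zyg is None:
        return "NA"
    return "MZ" if zyg.startswith("MZ") else "DZ"


class _Prepared:
    """Data and design assembled for one (spec, blocks) pair.

    Families are grouped by (dataset, zygosity group, roles, observed
    mask); each group stores stacked observed phenotypes and mean design
    tensors so a likelihood evaluation is a handful of small dense ops.
    All phenotypes/covariates are standardized here.
    """

    def __init__(self, spec: TwinModelSpec, blocks: list[FamilyBlock],
                 region_names: Sequence[str]):
        self.spec = spec
        traits = spec.traits
        nt = len(traits)
        self.traits = traits
        self.n_traits = nt
        tidx = [list(region_names).index(t) for t in traits]

        kept = []
        for b in blocks:
            ph = b.phenotypes[:, tidx]
            if np.isnan(ph).all():
                continue
            kept.append((b, ph))
        if not kept:
            raise FitError("no family blocks with observed trait values")
        self.datasets = sorted({b.dataset for b, _ in kept})

        # Internal scale: each trait is expressed as the residual from a
        # rough OLS fit (per-dataset intercept + model covariates, raw
        # units), divided by the residual SD. The likelihood's own mean
        # parameters then describe O(1) corrections on top of that offset,
        # keeping the optimisation well conditioned however strong the
        # covariate effects are; raw-scale estimates add the offset back.
        covs = list(spec.covariates)
        cov_cols = {"age": 0, "sex": 1, "icv": 2}
        ds_code = {d: i for i, d in enumerate(self.datasets)}
        n_ds = len(self.datasets)
        self.t_mean = np.zeros(nt)
        self.t_sd = np.ones(nt)
        self._ols = []   # per trait: (intercept per dataset, slope per covariate)
        for j in range(nt):
            vals, rows = [], []
            for b, ph in kept:
                for i in range(b.n_members):
                    v = ph[i, j]
                    if np.isnan(v):
                        continue
                    vals.append(v)
                    dummies = [0.0] * n_ds
                    dummies[ds_code[b.dataset]] = 1.0
                    rows.append(dummies + [b.covariates[i, cov_cols[c]]
                                           for c in covs])
            y = np.asarray(vals)
            self.t_mean[j] = y.mean()
            X = np.asarray(rows)
            if len(y) > X.shape[1] + 2:
                beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
                resid = y - X @ beta_ols
                sd = resid.std(ddof=1)
            else:
                beta_ols = np.r_[np.full(n_ds, y.mean()), np.zeros(len(covs))]
                sd = y.std(ddof=1)
            self.t_sd[j] = sd if sd > 0 else 1.0
            self._ols.append((
                {d: float(beta_ols[ds_code[d]]) for d in self.datasets},
                {c: float(beta_ols[n_ds + ci]) for ci, c in enumerate(covs)},
            ))
        self._ds_code = ds_code
        self._cov_cols = cov_cols
        # change-of-variables term: -2lnL is always reported on the raw
        # mm^3 scale so values are comparable across fits whose internal
        # standardizations differ (e.g. covariate-drop LRTs)
        n_obs = np.zeros(nt)
        for b, ph in kept:
            n_obs += (~np.isnan(ph)).sum(axis=0)
        self.log_jacobian = float(2.0 * np.sum(n_obs * np.log(self.t_sd)))
        if covs:
            allc = np.concatenate([b.covariates for b, _ in kept], axis=0)
            self.c_mean = {c: allc[:, cov_cols[c]].mean() for c in covs}
            self.c_sd = {}
            for c in covs:
                sd = allc[:, cov_cols[c]].std(ddof=1)
                self.c_sd[c] = sd if sd > 0 else 1.0
        else:
            self.c_mean, self.c_sd = {}, {}

        # ---- parameter names
        self.vgroups = ["pooled"] if spec.equate_datasets else self.datasets
        mean_names: list[str] = []
        if spec.kind == "variance_components":
            for d in self.datasets:
                for t in traits:
                    mean_names.append(f"mu[{d}|{t}]")
            for c in covs:
                for d in self.datasets:
                    for t in traits:
                        mean_names.append(f"b_{c}[{d}|{t}]")
        else:  # saturated
            zygs = sorted({b.zygosity_group for b, _ in kept
                           if b.zygosity_group is not None})
            self.zygs_by_ds = {
                d: sorted({b.zygosity_group for b, _ in kept
                           if b.dataset == d and b.zygosity_group is not None})
                for d in self.datasets}
            self.has_sib = {
                d: any("sibling" in b.roles for b, _ in kept if b.dataset == d)
                for d in self.datasets}
            for d in self.datasets:
                for z in self.zygs_by_ds[d]:
                    for ro in ("twin1", "twin2"):
                        mean_names.append(f"mu[{d}|{z}|{ro}]")
                if self.has_sib[d]:
                    mean_names.append(f"mu[{d}|sib]")
            for c in covs:
                for d in self.datasets:
                    mean_names.append(f"b_{c}[{d}]")
        self.mean_names = mean_names

        cov_names: list[str] = []
        if spec.kind == "variance_components":
            comps = [c for c in ("A", "C", "D", "E") if c in spec.components]
            self.comps = comps
            for g in self.vgroups:
                for comp in comps:
                    for t in traits:
                        cov_names.append(f"{comp}[{g}|{t}]")
                    if nt == 2:
                        cov_names.append(f"cov{comp}[{g}]")
        else:
            for d in self.datasets:
                for z in self.zygs_by_ds[d]:
                    for ro in ("twin1", "twin2"):
                        cov_names.append(f"v[{d}|{z}|{ro}]")
                    cov_names.append(f"c[{d}|{z}]")
                if self.has_sib[d]:
                    cov_names.append(f"v[{d}|sib]")
                    cov_names.append(f"cts[{d}]")
        self.cov_names = cov_names
        self.names = mean_names + cov_names

        ties, fixes = dict(spec.ties), {}
        for k, v in spec.fixes.items():
            if k.startswith("__component__"):
                comp = k[len("__component__"):]
                for n in cov_names:
                    if n.startswith(f"{comp}[") or n.startswith(f"cov{comp}["):
                        fixes[n] = v
            else:
                fixes[k] = v
        mean_set = set(mean_names)
        mean_ties = {k: v for k, v in ties.items() if k in mean_set}
        cov_ties = {k: v for k, v in ties.items() if k not in mean_set}
        mean_fixes = {k: v for k, v in fixes.items() if k in mean_set}
        cov_fixes = {k: v for k, v in fixes.items() if k not in mean_set}
        self.mean_map = _ParamMap(mean_names, mean_ties, mean_fixes)
        self.cov_map = _ParamMap(cov_names, cov_ties, cov_fixes)
        self.n_mean = len(mean_names)
        self.mean_index = {n: i for i, n in enumerate(mean_names)}

        # the mean model is linear, so the optimal coefficients given the
        # covariance parameters solve a GLS system; the likelihood is
        # concentrated over them. Full mean vector = M @ beta_free + m0.
        n_free_mean = self.mean_map.n_free
        M = np.zeros((self.n_mean, n_free_mean))
        m0 = np.zeros(self.n_mean)
        for i, n in enumerate(mean_names):
            c = self.mean_map.canon[n]
            if c in self.mean_map.fixes:
                m0[i] = self.mean_map.fixes[c]
            else:
                M[i, self.mean_map.free_index[c]] = 1.0
        self._M, self._m0 = M, m0

        # ---- group the blocks
        groups: dict[tuple, dict] = {}
        for b, ph in kept:
            mask = ~np.isnan(ph)            # (m, nt)
            key = (b.dataset, b.zygosity_group, tuple(b.roles),
                   tuple(mask.ravel()))
            g = groups.setdefault(key, {"Y": [], "X": []})
            y = self._internal_y(b, ph).ravel()
            X = self._design_rows(b)        # (m*nt, n_mean)
            flat = mask.ravel()
            g["Y"].append(y[flat] - X[flat] @ m0)
            g["X"].append(X[flat] @ M)
        self.groups = []
        for (ds, zyg, roles, flat_mask), g in groups.items():
            Y = np.array(g["Y"])
            X = np.array(g["X"])
            n, k = Y.shape
            self.groups.append({
                "dataset": ds, "zyg": zyg, "roles": roles,
                "mask": np.array(flat_mask, dtype=bool),
                "Y": Y,                          # (n, k): offset removed
                "X": X,                          # (n, k, n_free_mean)
                "Xt": X.transpose(1, 0, 2).reshape(k, n * n_free_mean),
                "n": n,
                "k": k,
            })
        self._bases = None

    # ---- internal scale ---------------------------------------------------
    def _internal_y(self, b: FamilyBlock, ph: np.ndarray) -> np.ndarray:
        """Phenotypes minus the per-trait OLS offset, in residual-SD units."""
        out = np.empty_like(ph, dtype=float)
        for j in range(self.n_traits):
            intercepts, slopes = self._ols[j]
            offset = intercepts[b.dataset]
            for c in self.spec.covariates:
                offset = offset + slopes[c] * b.covariates[:, self._cov_cols[c]]
            out[:, j] = (ph[:, j] - offset) / self.t_sd[j]
        return out

    # ---- mean design ------------------------------------------------------
    def _design_rows(self, b: FamilyBlock) -> np.ndarray:
        spec = self.spec
        nt = self.n_traits
        m = b.n_members
        X = np.zeros((m * nt, self.n_mean))
        cov_cols = {"age": 0, "sex": 1, "icv": 2}
        for i in range(m):
            for j, t in enumerate(self.traits):
                row = i * nt + j
                if spec.kind == "variance_components":
                    X[row, self.mean_index[f"mu[{b.dataset}|{t}]"]] = 1.0
                    for c in spec.covariates:
                        x = (b.covariates[i, cov_cols[c]] - self.c_mean[c]) / self.c_sd[c]
                        X[row, self.mean_index[f"b_{c}[{b.dataset}|{t}]"]] = x
                else:
                    role = b.roles[i]
                    if role == "sibling":
                        name = f"mu[{b.dataset}|sib]"
                    else:
                        name = f"mu[{b.dataset}|{b.zygosity_group}|{role}]"
                    X[row, self.mean_index[name]] = 1.0
                    for c in spec.covariates:
                        x = (b.covariates[i, cov_cols[c]] - self.c_mean[c]) / self.c_sd[c]
                        X[row, self.mean_index[f"b_{c}[{b.dataset}]"]] = x
        return X

    # ---- covariance structure --------------------------------------------
    def _sigma_full(self, params: dict, dataset: str, zyg: str | None,
                    roles: tuple) -> np.ndarray:
        spec = self.spec
        m = len(roles)
        nt = self.n_traits
        if spec.kind == "variance_components":
            g = "pooled" if spec.equate_datasets else dataset
            mz = zyg is not None and zyg.startswith("MZ")
            sigma = np.zeros((m * nt, m * nt))
            for comp in self.comps:
                if comp == "A":
                    K = np.full((m, m), spec.dz_a)
                    np.fill_diagonal(K, 1.0)
                    if mz and m >= 2 and roles[0] == "twin1" and roles[1] == "twin2":
                        K[0, 1] = K[1, 0] = 1.0
                elif comp == "D":
                    K = np.full((m, m), 0.25)
                    np.fill_diagonal(K, 1.0)
                    if mz and m >= 2 and roles[0] == "twin1" and roles[1] == "twin2":
                        K[0, 1] = K[1, 0] = 1.0
                elif comp == "C":
                    K = np.ones((m, m))
                else:  # E
                    K = np.eye(m)
                if nt == 1:
                    S = np.array([[params[f"{comp}[{g}|{self.traits[0]}]"]]])
                else:
                    v1 = params[f"{comp}[{g}|{self.traits[0]}]"]
                    v2 = params[f"{comp}[{g}|{self.traits[1]}]"]
                    cv = params[f"cov{comp}[{g}]"]
                    S = np.array([[v1, cv], [cv, v2]])
                sigma += np.kron(K, S)
            return sigma
        # saturated: single trait
        sigma = np.zeros((m, m))
        for i, ro in enumerate(roles):
            if ro == "sibling":
                sigma[i, i] = params[f"v[{dataset}|sib]"]
            else:
                sigma[i, i] = params[f"v[{dataset}|{zyg}|{ro}]"]
        for i in range(m):
            for j in range(i + 1, m):
                if "sibling" in (roles[i], roles[j]):
                    sigma[i, j] = sigma[j, i] = params[f"cts[{dataset}]"]
                else:
                    sigma[i, j] = sigma[j, i] = params[f"c[{dataset}|{zyg}]"]
        return sigma

    # ---- linear covariance structure --------------------------------------
    def _sigma_bases(self):
        """Per-group decomposition Sigma(theta) = B0 + sum_j theta_j * B_j.

        The expected covariance is linear in every covariance parameter
        (direct parameterisation), so the bases are exact and enable an
        analytic gradient of the concentrated -2lnL via the envelope
        theorem. Computed lazily, once.
        """
        if getattr(self, "_bases", None) is not None:
            return self._bases
        J = self.cov_map.n_free
        bases = []
        zero = self.cov_map.expand(np.zeros(J))
        for g in self.groups:
            ix = np.ix_(g["mask"], g["mask"])
            B0 = self._sigma_full(zero, g["dataset"], g["zyg"], g["roles"])[ix]
            Bj = np.empty((J, B0.shape[0], B0.shape[0]))
            for j in range(J):
                e = np.zeros(J)
                e[j] = 1.0
                Bj[j] = self._sigma_full(self.cov_map.expand(e), g["dataset"],
                                         g["zyg"], g["roles"])[ix] - B0
            bases.append((B0, Bj))
        self._bases = bases
        return bases

    # ---- objective (concentrated over the mean coefficients) --------------
    def _gls_pass(self, params: dict):
        """One sweep over the groups: GLS normal equations + log-dets."""
        p = self._M.shape[1]
        A = np.zeros((p, p))
        bvec = np.zeros(p)
        sum_v2 = 0.0
        const = 0.0
        for g in self.groups:
            sig = self._sigma_full(params, g["dataset"], g["zyg"], g["roles"])
            sig = sig[np.ix_(g["mask"], g["mask"])]
            try:
                L = np.linalg.cholesky(sig)
            except np.linalg.LinAlgError:
                return None
            n, k = g["n"], g["k"]
            V = linalg.solve_triangular(L, g["Y"].T, lower=True)      # (k, n)
            const += n * (k * _LOG_2PI + 2.0 * np.log(np.diag(L)).sum())
            sum_v2 += float((V * V).sum())
            if p:
                U = linalg.solve_triangular(L, g["Xt"], lower=True)
                U = U.reshape(k, n, p)
                A += np.einsum("knp,knq->pq", U, U)
                bvec += np.einsum("knp,kn->p", U, V)
        return A, bvec, sum_v2, const

    def minus2ll_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Concentrated -2lnL and its exact gradient.

        Sigma is linear in the covariance parameters, so d(-2lnL)/dtheta_j
        per group is tr[(n*Sigma^-1 - Sigma^-1 S Sigma^-1) B_j] with S the
        residual scatter; the concentrated mean coefficients contribute no
        extra term (envelope theorem).
        """
        bases = self._sigma_bases()
        J = self.cov_map.n_free
        p = self._M.shape[1]
        A = np.zeros((p, p))
        bvec = np.zeros(p)
        sum_v2 = 0.0
        const = 0.0
        cache = []
        for g, (B0, Bj) in zip(self.groups, bases):
            sig = B0 + np.tensordot(theta, Bj, axes=1) if J else B0
            try:
                L = np.linalg.cholesky(sig)
            except np.linalg.LinAlgError:
                return _BIG, np.zeros(J)
            n, k = g["n"], g["k"]
            V = linalg.solve_triangular(L, g["Y"].T, lower=True)
            const += n * (k * _LOG_2PI + 2.0 * np.log(np.diag(L)).sum())
            sum_v2 += float((V * V).sum())
            U = None
            if p:
                U = linalg.solve_triangular(L, g["Xt"], lower=True).reshape(k, n, p)
                A += np.einsum("knp,knq->pq", U, U)
                bvec += np.einsum("knp,kn->p", U, V)
            cache.append((L, V, U))
        beta = self._solve_beta(A, bvec)
        quad = sum_v2 - 2.0 * float(bvec @ beta) + float(beta @ A @ beta)
        f = const + quad
        if not np.isfinite(f):
            return _BIG, np.zeros(J)
        grad = np.zeros(J)
        for g, (B0, Bj), (L, V, U) in zip(self.groups, bases, cache):
            rho = V - np.einsum("knp,p->kn", U, beta) if p else V
            S_w = rho @ rho.T
            W = linalg.solve_triangular(L, np.eye(L.shape[0]), lower=True)
            Cg = W.T @ (g["n"] * np.eye(L.shape[0]) - S_w) @ W
            if J:
                grad += np.einsum("kl,jkl->j", Cg, Bj)
        return f, grad

    def _solve_beta(self, A: np.ndarray, bvec: np.ndarray) -> np.ndarray:
        if A.shape[0] == 0:
            return np.zeros(0)
        try:
            return linalg.solve(A, bvec, assume_a="pos")
        except (np.linalg.LinAlgError, linalg.LinAlgError, ValueError):
            return np.linalg.lstsq(A, bvec, rcond=None)[0]

    def minus2ll(self, theta: np.ndarray) -> float:
        params = self.cov_map.expand(theta)
        out = self._gls_pass(params)
        if out is None:
            return _BIG
        A, bvec, sum_v2, const = out
        beta = self._solve_beta(A, bvec)
        quad = sum_v2 - 2.0 * float(bvec @ beta) + float(beta @ A @ beta)
        total = const + quad
        if not np.isfinite(total):
            return _BIG
        return total

    def full_params(self, theta: np.ndarray) -> dict[str, float]:
        """Complete named parameter set (GLS means + covariance params)."""
        params = self.cov_map.expand(theta)
        out = self._gls_pass(params)
        full = dict(params)
        if out is not None:
            beta = self._solve_beta(out[0], out[1])
            mean_full = self._M @ beta + self._m0
            full.update({n: float(mean_full[i])
                         for i, n in enumerate(self.mean_names)})
        else:
            full.update({n: math.nan for n in self.mean_names})
        return full

    def minus2ll_from_blocks(self, theta: np.ndarray,
                             blocks: list[FamilyBlock],
                             region_names: Sequence[str]) -> float:
        """Reference path: same likelihood via per-block block_loglik."""
        full = self.full_params(theta)
        beta = np.array([full[n] for n in self.mean_names])
        tidx = [list(region_names).index(t) for t in self.traits]
        total = 0.0
        for b in blocks:
            ph = b.phenotypes[:, tidx]
            y = self._internal_y(b, ph).ravel()
            X = self._design_rows(b)
            mu = X @ beta
            sig = self._sigma_full(full, b.dataset, b.zygosity_group,
                                   tuple(b.roles))
            total += block_loglik(y, mu, sig)
        return -2.0 * total + self.log_jacobian

    # ---- initial values ----------------------------------------------------
    def initial(self) -> np.ndarray:
        # OLS residual moments seed the covariance parameters (the mean
        # coefficients themselves are concentrated out of the likelihood)
        p = self._M.shape[1]
        Xs = np.concatenate([g["X"].reshape(-1, p) for g in self.groups])
        ys = np.concatenate([g["Y"].ravel() for g in self.groups])
        if p:
            beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        else:
            beta = np.zeros(0)

        if self.spec.kind == "saturated":
            # ML per-group moments: exact MLE on complete data
            acc_v: dict[str, list] = {}
            acc_c: dict[str, list] = {}
            for g in self.groups:
                E = g["Y"] - g["X"] @ beta
                # map observed columns back to members (single trait)
                cols = [i for i, ok in enumerate(g["mask"]) if ok]
                for ci, member in enumerate(cols):
                    ro = g["roles"][member]
                    name = (f"v[{g['dataset']}|sib]" if ro == "sibling"
                            else f"v[{g['dataset']}|{g['zyg']}|{ro}]")
                    acc_v.setdefault(name, []).append(E[:, ci] ** 2)
                for ci in range(len(cols)):
                    for cj in range(ci + 1, len(cols)):
                        ri, rj = g["roles"][cols[ci]], g["roles"][cols[cj]]
                        if "sibling" in (ri, rj):
                            name = f"cts[{g['dataset']}]"
                        else:
                            name = f"c[{g['dataset']}|{g['zyg']}]"
                        acc_c.setdefault(name, []).append(E[:, ci] * E[:, cj])
            full_cov = {}
            for n in self.cov_names:
                src = acc_v.get(n) or acc_c.get(n)
                if src is not None:
                    full_cov[n] = float(np.mean(np.concatenate(src)))
                else:
                    full_cov[n] = 0.5 if n.startswith("v[") else 0.1
                if n.startswith("v[") and full_cov[n] <= 1e-6:
                    full_cov[n] = 1e-3
            return self.cov_map.collapse(full_cov)

        # variance components: moment estimates from pair residual products
        nt = self.n_traits
        stats_acc = {"mz_cross": [], "dz_cross": [], "var": [[] for _ in range(nt)],
                     "mz_x": [], "dz_x": [], "within_x": []}
        for g in self.groups:
            E = g["Y"] - g["X"] @ beta
            cols = [i for i, ok in enumerate(g["mask"]) if ok]
            m = len(g["roles"])
            colpos = {c: (c // nt, c % nt) for c in cols}
            zc = _zyg_class(g["zyg"])
            for ci, c in enumerate(cols):
                mem, tr = colpos[c]
                stats_acc["var"][tr].append(E[:, ci] ** 2)
            for ci in range(len(cols)):
                for cj in range(ci + 1, len(cols)):
                    (mi, ti), (mj, tj) = colpos[cols[ci]], colpos[cols[cj]]
                    prod = E[:, ci] * E[:, cj]
                    if mi == mj and ti != tj:
                        stats_acc["within_x"].append(prod)
                    elif mi != mj and ti == tj:
                        key = "mz_cross" if zc == "MZ" else "dz_cross"
                        stats_acc[key].append(prod)
                    elif mi != mj and ti != tj:
                        key = "mz_x" if zc == "MZ" else "dz_x"
                        stats_acc[key].append(prod)

        def pool(lst, default=0.0):
            if not lst:
                return default
            return float(np.mean(np.concatenate(lst)))

        Vp = [pool(stats_acc["var"][j], 1.0) for j in range(nt)]
        Vbar = float(np.mean(Vp))
        floor = 0.05 * max(Vbar, 1e-12)
        cmz = pool(stats_acc["mz_cross"])
        cdz = pool(stats_acc["dz_cross"])
        A0 = max(2.0 * (cmz - cdz), floor)
        C0 = max(2.0 * cdz - cmz, 0.0)
        has_a = "A" in self.comps
        has_c = "C" in self.comps
        if not has_c:
            A0 = max(cmz if cmz > 0 else A0, floor)
            C0 = 0.0
        if not has_a:
            C0 = max(cmz, floor)
            A0 = 0.0
        E0 = [max(v - (A0 + C0), floor) for v in Vp]
        full_cov = {}
        for g in self.vgroups:
            for j, t in enumerate(self.traits):
                scale = Vp[j] / max(A0 + C0 + E0[j], 1e-12)
                if has_a:
                    full_cov[f"A[{g}|{t}]"] = A0 * scale
                if has_c:
                    full_cov[f"C[{g}|{t}]"] = C0 * scale
                if "D" in self.comps:
                    full_cov[f"D[{g}|{t}]"] = 0.0
                full_cov[f"E[{g}|{t}]"] = E0[j] * scale
            if nt == 2:
                xmz = pool(stats_acc["mz_x"])
                xdz = pool(stats_acc["dz_x"])
                xwithin = pool(stats_acc["within_x"])
                covA0 = 2.0 * (xmz - xdz) if (has_a and has_c) else (xmz if has_a else 0.0)
                covC0 = (2.0 * xdz - xmz) if has_c else 0.0
                covE0 = xwithin - covA0 - covC0
                # shrink cross-covariances to keep the start positive definite
                vA = full_cov.get(f"A[{g}|{self.traits[0]}]", 0.0) * \
                    full_cov.get(f"A[{g}|{self.traits[1]}]", 0.0)
                vC = full_cov.get(f"C[{g}|{self.traits[0]}]", 0.0) * \
                    full_cov.get(f"C[{g}|{self.traits[1]}]", 0.0)
                vE = full_cov[f"E[{g}|{self.traits[0]}]"] * \
                    full_cov[f"E[{g}|{self.traits[1]}]"]

                def clip(cv, bound):
                    lim = 0.9 * math.sqrt(max(bound, 0.0))
                    return float(np.clip(cv, -lim, lim))

                if has_a:
                    full_cov[f"covA[{g}]"] = clip(covA0, vA)
                if has_c:
                    full_cov[f"covC[{g}]"] = clip(covC0, vC)
                if "D" in self.comps:
                    full_cov[f"covD[{g}]"] = 0.0
                full_cov[f"covE[{g}]"] = clip(covE0, vE)
        return self.cov_map.collapse(full_cov)

    # ---- back-transformation ----------------------------------------------
    def raw_estimates(self, params: dict[str, float]) -> dict[str, float]:
        """Map internal (standardized-scale) parameters back to mm^3 units."""
        out = {}
        t_of = {t: j for j, t in enumerate(self.traits)}

        def trait_of(name: str) -> int:
            if self.spec.kind == "saturated" or self.n_traits == 1:
                return 0
            inner = name[name.index("[") + 1:-1]
            t = inner.split("|")[-1]
            return t_of.get(t, 0)

        # model-part slopes on raw covariate scale (before adding the OLS
        # offset slopes absorbed at standardization time)
        model_slope: dict[str, float] = {}
        for n, v in params.items():
            if n.startswith("b_"):
                c = n[2:n.index("[")]
                j = trait_of(n)
                model_slope[n] = v * self.t_sd[j] / self.c_sd[c]
        for n, v in params.items():
            if n.startswith("mu["):
                j = trait_of(n)
                d = n[n.index("[") + 1:-1].split("|")[0]
                ols_int, _ = self._ols[j]
                shift = 0.0
                for c in self.spec.covariates:
                    if self.spec.kind == "variance_components":
                        bname = f"b_{c}[{d}|{self.traits[j]}]"
                    else:
                        bname = f"b_{c}[{d}]"
                    shift += model_slope[bname] * self.c_mean[c]
                out[n] = ols_int.get(d, self.t_mean[j]) + self.t_sd[j] * v - shift
            elif n.startswith("b_"):
                c = n[2:n.index("[")]
                j = trait_of(n)
                out[n] = self._ols[j][1].get(c, 0.0) + model_slope[n]
            elif n.startswith(("cov", "c[", "cts[")):
                if self.n_traits == 2 and n.startswith("cov"):
                    out[n] = v * self.t_sd[0] * self.t_sd[1]
                else:
                    out[n] = v * self.t_sd[0] ** 2
            else:  # variances / components: same trait twice
                j = trait_of(n)
                out[n] = v * self.t_sd[j] ** 2
        return out

    def standardized(self, params: dict[str, float]) -> dict[str, float]:
        """Scale-free summaries: standardized components, correlations."""
        out = {}
        if self.spec.kind == "variance_components":
            for g in self.vgroups:
                for j, t in enumerate(self.traits):
                    tot = sum(params[f"{c}[{g}|{t}]"] for c in self.comps)
                    for c in self.comps:
                        out[f"std_{c}[{g}|{t}]"] = params[f"{c}[{g}|{t}]"] / tot
                    out[f"V[{g}|{t}]"] = tot * self.t_sd[j] ** 2
                if self.n_traits == 2:
                    t1, t2 = self.traits
                    v1 = sum(params[f"{c}[{g}|{t1}]"] for c in self.comps)
                    v2 = sum(params[f"{c}[{g}|{t2}]"] for c in self.comps)
                    covp = sum(params[f"cov{c}[{g}]"] for c in self.comps)
                    out[f"r_ph[{g}]"] = covp / math.sqrt(v1 * v2)
                    for c in self.comps:
                        a1, a2 = params[f"{c}[{g}|{t1}]"], params[f"{c}[{g}|{t2}]"]
                        if a1 > 0 and a2 > 0:
                            out[f"r_{c}[{g}]"] = params[f"cov{c}[{g}]"] / math.sqrt(a1 * a2)
                        else:
                            out[f"r_{c}[{g}]"] = math.nan
        else:
            # twin correlations per zygosity group from saturated structure
            for d in self.datasets:
                for z in self.zygs_by_ds[d]:
                    v1 = params[f"v[{d}|{z}|twin1]"]
                    v2 = params[f"v[{d}|{z}|twin2]"]
                    if v1 > 0 and v2 > 0:
                        out[f"r[{d}|{z}]"] = params[f"c[{d}|{z}]"] / math.sqrt(v1 * v2)
        return out


# ---------------------------------------------------------------------------
# fitting

def _prepare(spec: TwinModelSpec, cohort: Cohort) -> tuple[_Prepared, list[FamilyBlock]]:
    blocks = family_blocks(cohort)
    prep = _Prepared(spec, blocks, cohort.region_names)
    return prep, blocks


def fit(
    spec: TwinModelSpec,
    cohort: Cohort,
    *,
    n_starts: int = 5,
    jitter: float = 0.2,
    tol: float = 1e-8,
    seed: int = 0,
) -> FitResult:
    """Maximise the FIML likelihood of ``spec`` over all family blocks.

    Multi-start quasi-Newton optimisation: the first start uses
    moment-based initial values, the rest perturb them multiplicatively by
    up to ``jitter``. A failed fit is returned flagged (``converged
    False``), never silently dropped.
    """
    blocks = family_blocks(cohort)
    if spec.kind == "variance_components":
        free_comps = {c for c in spec.components
                      if f"__component__{c}" not in spec.fixes}
        if {"A", "C"} <= free_comps:
            zclasses = {_zyg_class(b.zygosity_group) for b in blocks
                        if len(b.roles) >= 2}
            if not {"MZ", "DZ"} <= zclasses:
                raise FitError(
                    "A and C are jointly free but the cohort lacks both MZ and "
                    "DZ pairs (model not identified)")
    prep = _Prepared(spec, blocks, cohort.region_names)
    theta0 = prep.initial()
    rng = np.random.default_rng(seed)
    best = None
    n_eval = 0
    for s in range(max(1, n_starts)):
        start = theta0 if s == 0 else theta0 * (
            1.0 + rng.uniform(-jitter, jitter, size=theta0.shape))
        res = optimize.minimize(prep.minus2ll_and_grad, start, jac=True,
                                method="L-BFGS-B",
                                options={"ftol": tol, "gtol": 1e-9,
                                         "maxiter": 2000})
        n_eval += res.nfev
        if best is None or res.fun < best.fun:
            best = res
    if not best.success or best.fun >= _BIG / 2:
        # refinement with finite-difference gradients: covers rare cases
        # where extreme scaling erodes the analytic-gradient precision
        res = optimize.minimize(prep.minus2ll, best.x, method="Nelder-Mead",
                                options={"fatol": tol, "xatol": 1e-8,
                                         "maxiter": 4000})
        n_eval += res.nfev
        if res.fun <= best.fun:
            best = res
    converged = bool(best.success) and best.fun < _BIG / 2
    params = prep.full_params(best.x)
    result = FitResult(
        spec=spec,
        estimates=prep.raw_estimates(params),
        minus2LL=float(best.fun) + prep.log_jacobian,
        n_params=prep.cov_map.n_free + prep.mean_map.n_free,
        converged=converged,
        standardized=prep.standardized(params),
        diagnostics={"message": str(best.message), "n_eval": n_eval,
                     "n_starts": n_starts},
    )
    result._internal = (prep, best.x.copy())
    return result


def lrt(full: FitResult, constrained: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of a constrained model nested in a full one.

    Returns (statistic, df, p). Negative statistics within numerical
    tolerance are clipped to zero; larger negative values indicate a
    non-nested or non-converged comparison and raise.
    """
    df = full.n_params - constrained.n_params
    stat = constrained.minus2LL - full.minus2LL
    if df == 0 and abs(stat) <= 1e-6:
        return 0.0, 0, 1.0  # identical models
    if df <= 0:
        raise ValidationError("constrained model must have fewer free parameters")
    if stat < -1e-4:
        raise FitError(
            f"constrained fit beat the full fit by {-stat:.3g}: models not "
            "nested or optimisation failed")
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df))
    return float(stat), int(df), p


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals

def _quantity_fn(prep: _Prepared, quantity) -> Callable[[dict], float]:
    if callable(quantity):
        return quantity

    def fn(params: dict) -> float:
        std = prep.standardized(params)
        if quantity in std:
            return std[quantity]
        # allow bare names like "std_A" when unambiguous
        hits = [k for k in std if k.startswith(quantity + "[")]
        if len(hits) == 1:
            return std[hits[0]]
        raise ValidationError(
            f"quantity {quantity!r} not found or ambiguous; "
            f"available: {sorted(std)}")
    return fn


def profile_ci(
    fit_result,
    quantity,
    *,
    cohort: Cohort | None = None,
    level: float = 0.95,
    search_halfwidth: float = 2.0,
    tol: float = 1e-4,
) -> tuple[float, float]:
    """Profile-likelihood interval for a standardized quantity.

    A bound b solves: min -2lnL subject to quantity = b equals the
    unconstrained minimum plus the chi-square(1) critical value (3.84 at
    95%). The constrained refits use SLSQP with warm starts; bounds are
    bracketed outward from the estimate and solved by Brent's method. A
    bound that cannot be bracketed within ``search_halfwidth`` of the
    estimate is reported one-sided as +/-inf.

    ``fit_result`` may also be a TwinModelSpec, in which case ``cohort``
    must be given and the model is fitted first.
    """
    if isinstance(fit_result, TwinModelSpec):
        if cohort is None:
            raise ValidationError("profile_ci(spec, ...) requires cohort=")
        fit_result = fit(fit_result, cohort)
    prep, theta_hat = fit_result._internal
    qfn = _quantity_fn(prep, quantity)
    # profiling works on the internal-scale objective; remove the constant
    # raw-scale Jacobian from the reference minimum
    m2ll_min = fit_result.minus2LL - prep.log_jacobian
    crit = float(stats.chi2.ppf(level, 1))
    q_hat = qfn(prep.cov_map.expand(theta_hat))

    warm = {"x": theta_hat.copy()}

    def profile(b: float) -> float:
        cons = {"type": "eq",
                "fun": lambda th: qfn(prep.cov_map.expand(th)) - b}
        res = optimize.minimize(prep.minus2ll_and_grad, warm["x"], jac=True,
                                method="SLSQP", constraints=[cons],
                                options={"ftol": 1e-10, "maxiter": 500})
        val = res.fun
        if (not res.success) or abs(qfn(prep.cov_map.expand(res.x)) - b) > 1e-6:
            res2 = optimize.minimize(prep.minus2ll_and_grad, theta_hat, jac=True,
                                     method="SLSQP", constraints=[cons],
                                     options={"ftol": 1e-10, "maxiter": 500})
            if res2.fun < val and abs(qfn(prep.cov_map.expand(res2.x)) - b) <= 1e-6:
                res, val = res2, res2.fun
            elif abs(qfn(prep.cov_map.expand(res.x)) - b) > 1e-6:
                return _BIG  # constraint unreachable: quantity fixed by design
        warm["x"] = res.x.copy()
        return val

    def g(b: float) -> float:
        return profile(b) - (m2ll_min + crit)

    def find_bound(direction: float) -> float:
        step = 0.02
        prev_b = q_hat
        prev_g = -crit
        b = q_hat
        for _ in range(60):
            step = min(step * 1.6, 0.25)
            b = b + direction * step
            if abs(b - q_hat) > search_halfwidth:
                return direction * math.inf
            gb = g(b)
            if gb > 0.0:
                if gb >= _BIG / 2:
                    return q_hat  # quantity pinned by construction
                lo, hi = (prev_b, b) if direction > 0 else (b, prev_b)
                return float(optimize.brentq(g, lo, hi, xtol=tol))
            prev_b, prev_g = b, gb
        return direction * math.inf

    lower = find_bound(-1.0)
    warm["x"] = theta_hat.copy()
    upper = find_bound(+1.0)
    return (lower, upper)
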