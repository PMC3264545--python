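"""Multi-centrality hub detection by two-round model-based clustering.

Proteins are clustered on their six max-normalized centrality values with
finite Gaussian mixtures.  For each candidate covariance family and component
count the mixture is fitted by EM with several seeded restarts, and the
(family, K) pair maximizing the BIC — in the mclust sign convention,
``2 log L - p log n`` — is retained.  The component whose mean profile is
highest across the six indices is the "central" cluster; a second clustering
round on that cluster alone isolates the multi-centrality hubs.

:class:`BICGaussianMixture` and :class:`HubDetector` are scikit-learn style
estimators (``fit``/``fit_predict``, fitted attributes with a trailing
underscore) and compose with sklearn tooling; the module-level functions
``fit_mixture_bic``, ``select_central_cluster`` and ``detect_hubs`` are thin
wrappers kept for pipeline use.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_is_fitted

from .centrality import NORM_LABELS

logger = logging.getLogger(__name__)

#: Candidate covariance structures, sklearn names.  The mclust-tradition
#: labels are recorded as aliases: "spherical" ~ EII/VII, "diag" ~ diagonal
#: families, "full" ~ unconstrained ellipsoidal (VVV; the equal-shape
#: ellipsoidal family VEV has no exact sklearn counterpart).  The default
#: set holds the per-component-volume structures: centrality tables carry
#: thousands of near-duplicate peripheral profiles next to a sparse central
#: cloud, and a shared-covariance ("tied") model — whose single scale gets
#: pinned to the duplicate-heavy bulk — degenerates into shattering the
#: sparse region one protein per component.  "tied" remains selectable.
DEFAULT_FAMILIES = ("spherical", "diag", "full")

MCLUST_ALIASES = {
    "spherical": "EII/VII (spherical)",
    "diag": "EEI..VVI (diagonal)",
    "tied": "EEE (ellipsoidal, equal)",
    "full": "VVV (ellipsoidal, unconstrained)",
}


class MixtureFitError(RuntimeError):
    """All candidate mixture models failed to fit."""


@dataclass
class MixtureFit:
    """Summary of the BIC-best Gaussian mixture over centrality profiles."""

    family: str
    n_components: int
    bic: float
    assignments: pd.Series  # protein id -> component label
    component_means: pd.DataFrame  # one row per component, centrality columns
    bic_convention: str = "2*loglik - n_params*log(n) (maximized)"

    @property
    def family_alias(self) -> str:
        return MCLUST_ALIASES.get(self.family, self.family)


class BICGaussianMixture(BaseEstimator, ClusterMixin):
    """Gaussian mixture with covariance family and K chosen by BIC.

    Fits every combination of ``families`` x ``k_min..k_max`` with
    ``n_init`` seeded EM restarts each and keeps the fit maximizing
    ``2 log L - p log n``.  Degenerate candidates (singular covariances,
    EM failures) are skipped with a logged warning.

    Parameters
    ----------
    k_min, k_max : int
        Inclusive range of candidate component counts (capped at the number
        of samples at fit time).
    families : sequence of str
        sklearn ``covariance_type`` names to try.
    n_init : int
        EM restarts per candidate.
    reg_covar : float
        Ridge added to covariance diagonals to avert singularities.
    random_state : int or None
        Seed for the EM restarts; fixing it makes selection deterministic.

    Attributes
    ----------
    family_ : str
        Winning covariance family.
    n_components_ : int
        Winning number of components.
    bic_ : float
        BIC of the winner (maximize convention).
    labels_ : ndarray of shape (n_samples,)
        Component assignment of the training data.
    means_ : ndarray of shape (n_components_, n_features)
        Component means.
    mixture_ : sklearn.mixture.GaussianMixture
        The underlying winning fit.
    """

    def __init__(
        self,
        k_min: int = 1,
        k_max: int = 20,
        families: Sequence[str] = DEFAULT_FAMILIES,
        n_init: int = 10,
        reg_covar: float = 1e-6,
        random_state: int | None = 0,
    ):
        self.k_min = k_min
        self.k_max = k_max
        self.families = families
        self.n_init = n_init
        self.reg_covar = reg_covar
        self.random_state = random_state

    #: A fitted component whose variance collapses to within this factor of
    #: ``reg_covar`` in any direction sits on (near-)duplicate points; such a
    #: candidate is the regularized face of a singular covariance and is
    #: rejected, as an EM run without the ridge would be.
    degenerate_factor: float = 10.0

    #: Per-family scan heuristic: once a family's BIC has failed to improve
    #: for this many consecutive K the remaining (larger, costlier) K are
    #: not fitted.  BIC-in-K is quasi-concave on mixture data in practice,
    #: so a generous patience leaves the selection unchanged.
    k_patience: int = 5

    def _is_degenerate(self, gm: GaussianMixture, n: int) -> bool:
        """A candidate is degenerate when some component collapses onto too
        few points: its covariance hits the regularization floor in an
        eigen-direction (rank-deficient scatter) *and* it holds fewer
        effective points than dimensions + 1.  Large components whose
        thinnest direction is merely narrow (near-collinear indices over a
        dense mass) are honest structure and pass.
        """
        floor = self.degenerate_factor * self.reg_covar
        d = gm.means_.shape[1]
        sizes = gm.weights_ * n
        cov = gm.covariances_
        for k in range(gm.n_components):
            if gm.covariance_type == "full":
                eigs = np.linalg.eigvalsh(cov[k])
            elif gm.covariance_type == "tied":
                eigs = np.linalg.eigvalsh(cov)
            elif gm.covariance_type == "diag":
                eigs = np.asarray(cov[k])
            else:  # spherical
                eigs = np.asarray([cov[k]])
            if eigs.min() <= floor and sizes[k] < d + 1:
                return True
            if eigs.max() <= floor:
                # a point mass: every direction at the floor means the
                # component sits on exact-duplicate rows, however many
                return True
        return False

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D array with at least two rows")
        n = X.shape[0]
        k_hi = min(self.k_max, n)
        best = None
        best_degenerate = None
        rng = np.random.default_rng(self.random_state)
        restart_seeds = rng.integers(0, 2**31 - 1, size=self.n_init)
        for family in self.families:
            family_best = -np.inf
            since_improved = 0
            for k in range(self.k_min, k_hi + 1):
                # Restarts are screened individually: a collapsed covariance
                # inflates the likelihood by the regularization floor, so
                # best-of-restarts would systematically prefer singular
                # solutions.  The candidate's score is the best restart with
                # a valid (non-singular) covariance; if every restart
                # collapses the candidate itself is degenerate and skipped.
                cand = None
                cand_degen = None
                for rs in restart_seeds:
                    gm = GaussianMixture(
                        n_components=k,
                        covariance_type=family,
                        n_init=1,
                        reg_covar=self.reg_covar,
                        random_state=int(rs),
                        max_iter=300,
                    )
                    try:
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            gm.fit(X)
                        bic = -gm.bic(X)  # sklearn minimizes; flip sign
                    except (ValueError, np.linalg.LinAlgError) as exc:
                        logger.info("restart failed for %s K=%d: %s",
                                    family, k, exc)
                        continue
                    if not np.isfinite(bic):
                        continue
                    if self._is_degenerate(gm, n):
                        if cand_degen is None or bic > cand_degen[0]:
                            cand_degen = (bic, family, k, gm)
                        continue
                    if cand is None or bic > cand[0]:
                        cand = (bic, family, k, gm)
                if cand is None:
                    if cand_degen is not None:
                        logger.info(
                            "skipping candidate %s K=%d: singular/degenerate "
                            "component covariance in every restart", family, k
                        )
                        # among collapsed fits likelihoods are floor-dominated
                        # and incomparable; prefer the least complex one
                        if best_degenerate is None or (
                            (k, -bic) < (best_degenerate[2], -best_degenerate[0])
                        ):
                            best_degenerate = cand_degen
                    continue
                if cand[0] > family_best:
                    family_best = cand[0]
                    since_improved = 0
                else:
                    since_improved += 1
                    if since_improved >= self.k_patience:
                        # the family's BIC curve has been falling for a
                        # while; larger K only gets more expensive
                        break
                if best is None or cand[0] > best[0]:
                    best = cand
        if best is None and best_degenerate is not None:
            # e.g. exact-duplicate rows, where every candidate collapses
            logger.warning(
                "every candidate fit was degenerate; falling back to the "
                "BIC-best of them (%s, K=%d)",
                best_degenerate[1], best_degenerate[2],
            )
            best = best_degenerate
        if best is None:
            raise MixtureFitError("all (family, K) candidates failed to fit")
        self.bic_, self.family_, self.n_components_, self.mixture_ = best
        self.labels_ = self.mixture_.predict(X)
        self.means_ = self.mixture_.means_
        return self

    def predict(self, X):
        check_is_fitted(self, "mixture_")
        return self.mixture_.predict(np.asarray(X, dtype=float))


def _norm_columns(table: pd.DataFrame, columns: Sequence[str] | None) -> list[str]:
    if columns is not None:
        return list(columns)
    cols = [c for c in NORM_LABELS if c in table.columns]
    if not cols:
        raise ValueError(
            "table has no normalized centrality columns (*_norm); run "
            "centrality.normalize_max1 first"
        )
    return cols


def fit_mixture_bic(
    table: pd.DataFrame,
    k_range: tuple[int, int] = (1, 20),
    families: Sequence[str] = DEFAULT_FAMILIES,
    n_init: int = 10,
    seed: int | None = 0,
    columns: Sequence[str] | None = None,
) -> MixtureFit:
    """Fit the BIC-best Gaussian mixture to normalized centrality columns."""
    cols = _norm_columns(table, columns)
    est = BICGaussianMixture(
        k_min=k_range[0],
        k_max=k_range[1],
        families=families,
        n_init=n_init,
        random_state=seed,
    ).fit(table[cols].to_numpy())
    return MixtureFit(
        family=est.family_,
        n_components=est.n_components_,
        bic=est.bic_,
        assignments=pd.Series(est.labels_, index=table.index),
        component_means=pd.DataFrame(est.means_, columns=cols),
    )


def rank_components(fit: MixtureFit) -> list[int]:
    """Component labels ordered from most to least central.

    A component's score is the mean of its centrality means; ties are broken
    by larger mean betweenness, then by smaller cluster size.
    """
    means = fit.component_means
    sizes = fit.assignments.value_counts()
    b_col = "B_norm" if "B_norm" in means.columns else None

    def key(comp: int):
        overall = means.loc[comp].mean()
        b_mean = means.loc[comp, b_col] if b_col else 0.0
        return (overall, b_mean, -sizes.get(comp, 0))

    return sorted(means.index, key=key, reverse=True)


def select_central_cluster(fit: MixtureFit, table: pd.DataFrame) -> set[str]:
    """Members of the component with the highest mean normalized centrality."""
    if not fit.assignments.index.equals(table.index):
        raise ValueError("mixture fit and table cover different proteins")
    winner = rank_components(fit)[0]
    return set(fit.assignments.index[fit.assignments == winner])


@dataclass
class HubResult:
    """Outcome of the two-round clustering."""

    round1: MixtureFit
    round1_central_cluster: set[str]
    round2: MixtureFit | None
    hubs: set[str]
    audit: pd.DataFrame = field(default=None)  # per-round cluster means

    def to_json(self) -> str:
        def fit_summary(f: MixtureFit | None):
            if f is None:
                return None
            return {
                "family": f.family,
                "family_alias": f.family_alias,
                "n_components": f.n_components,
                "bic": f.bic,
                "bic_convention": f.bic_convention,
                "cluster_sizes": f.assignments.value_counts().to_dict(),
            }

        return json.dumps(
            {
                "hubs": sorted(self.hubs),
                "n_hubs": len(self.hubs),
                "round1": fit_summary(self.round1),
                "round1_central_cluster": sorted(self.round1_central_cluster),
                "round2": fit_summary(self.round2),
                "cluster_means": json.loads(
                    self.audit.to_json(orient="split")
                )
                if self.audit is not None
                else None,
            },
            indent=2,
        )


class HubDetector(BaseEstimator, ClusterMixin):
    """Two-round model-based clustering returning multi-centrality hubs.

    Round 1 clusters all proteins on the normalized centrality profile and
    keeps the most-central component; round 2 reclusters that component alone
    and keeps its most-central component as the hub set.  If the round-1
    central cluster is smaller than ``min_central_cluster`` the second round
    is skipped (with a warning) and that cluster is returned directly.

    Attributes (after ``fit``)
    --------------------------
    hubs_ : set of protein ids
    labels_ : ndarray, 1 for hubs and 0 otherwise, in input row order
    result_ : :class:`HubResult` with both rounds' fits and an audit table
    """

    def __init__(
        self,
        k_min: int = 1,
        k_max: int = 20,
        families: Sequence[str] = DEFAULT_FAMILIES,
        n_init: int = 10,
        seed: int | None = 0,
        min_central_cluster: int = 10,
        central_ratio: float = 0.5,
        columns: Sequence[str] | None = None,
    ):
        self.k_min = k_min
        self.k_max = k_max
        self.families = families
        self.n_init = n_init
        self.seed = seed
        self.min_central_cluster = min_central_cluster
        self.central_ratio = central_ratio
        self.columns = columns

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            raise TypeError(
                "HubDetector expects the centrality DataFrame (needs protein "
                "identifiers as index)"
            )
        cols = _norm_columns(X, self.columns)
        r1 = fit_mixture_bic(
            X,
            k_range=(self.k_min, self.k_max),
            families=self.families,
            n_init=self.n_init,
            seed=self.seed,
            columns=cols,
        )
        order = rank_components(r1)
        scores = r1.component_means.mean(axis=1)
        central = set(r1.assignments.index[r1.assignments == order[0]])
        # The BIC-best mixture often carves the central tail into several
        # components; the round-1 central set is every component at least
        # ``central_ratio`` times as central as the top one (and at least
        # min_central_cluster proteins, merging further down if needed).
        for comp in order[1:]:
            if (
                scores[comp] < self.central_ratio * scores[order[0]]
                and len(central) >= self.min_central_cluster
            ):
                break
            central |= set(r1.assignments.index[r1.assignments == comp])
        audit_rows = {"round1": r1.component_means}
        if len(central) < self.min_central_cluster:
            logger.warning(
                "round-1 central cluster has only %d proteins "
                "(< %d); skipping round 2",
                len(central),
                self.min_central_cluster,
            )
            r2, hubs = None, set(central)
        else:
            sub = X.loc[sorted(central)]
            r2 = fit_mixture_bic(
                sub,
                k_range=(self.k_min, min(self.k_max, len(sub))),
                families=self.families,
                n_init=self.n_init,
                seed=self.seed,
                columns=cols,
            )
            hubs = select_central_cluster(r2, sub)
            audit_rows["round2"] = r2.component_means
        audit = pd.concat(audit_rows, names=["round", "component"])
        self.result_ = HubResult(
            round1=r1,
            round1_central_cluster=central,
            round2=r2,
            hubs=hubs,
            audit=audit,
        )
        self.hubs_ = hubs
        self.labels_ = np.asarray([1 if p in hubs else 0 for p in X.index])
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def detect_hubs(
    table: pd.DataFrame,
    k_range: tuple[int, int] = (1, 20),
    families: Sequence[str] = DEFAULT_FAMILIES,
    n_init: int = 10,
    seed: int | None = 0,
    min_central_cluster: int = 10,
    central_ratio: float = 0.5,
    columns: Sequence[str] | None = None,
) -> HubResult:
    """Run the two-round hub detection; see :class:`HubDetector`."""
    det = HubDetector(
        k_min=k_range[0],
        k_max=k_range[1],
        families=families,
        n_init=n_init,
        seed=seed,
        min_central_cluster=min_central_cluster,
        central_ratio=central_ratio,
        columns=columns,
    ).fit(table)
    return det.result_
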