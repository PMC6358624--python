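"""Admixture dating from coancestry curves.

After restricted painting of a target cluster onto external donor groups,
the posterior copying probability per donor group at every site carries
ancestry linkage disequilibrium: following a two-way admixture pulse g
generations ago, the covariance (across site pairs at genetic distance d
Morgans, within chromosomes, averaged over target haplotypes) of copying
from group a at one site and group b at the other decays as

    cov_ab(d) ~ alpha (1 - alpha) * delta_a delta_b * exp(-g d),

where delta = f1 - f2 is the difference between the two ancestral sources'
expected copying profiles. Fitting exponentials to these coancestry curves
therefore yields the admixture date (g = 100 * lambda with lambda per cM),
and the rank-one structure of the fitted amplitude matrix yields the
admixture proportion and the two sources' donor-group compositions; the
source compositions are resolved by mapping the rank-one direction onto the
donor-group copying basis under simplex constraints. This is a simplified
form of the coancestry-curve machinery of GLOBETROTTER; its contract is
parameter recovery on truth-known simulations, not parity.

Calendar conversion assumes a fixed generation time (default 28 years) and
a reference (current) generation date of 1940 CE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .profiles import _simplex_nnls

__all__ = [
    "CoancestryCurve",
    "CurveSet",
    "ExponentialFit",
    "AdmixtureEvent",
    "compute_coancestry_curves",
    "null_site_permutation_curves",
    "fit_curve_exponential",
    "fit_shared_rate",
    "infer_two_way_event",
    "compare_one_vs_two_dates",
    "bootstrap_event_ci",
    "generations_to_year",
    "year_to_generations",
]

_RATE_GRID = np.arange(1, 61) / 100.0  # per cM; 1..60 per Morgan


@dataclass
class CoancestryCurve:
    """Binned ancestry covariance vs genetic distance for one group pair."""

    pair: tuple
    midpoints: np.ndarray  # cM
    values: np.ndarray
    weights: np.ndarray  # site-pair counts per bin

    def __post_init__(self) -> None:
        if np.any(self.midpoints <= 0) or np.any(np.diff(self.midpoints) <= 0):
            raise ValueError("bin midpoints must be positive and increasing")
        if not np.all(np.isfinite(self.values[self.weights > 0])):
            raise ValueError("non-finite curve values")


@dataclass
class ExponentialFit:
    """y(d) = intercept + amplitude * exp(-rate * d) (+ optional second
    component, rates ordered increasing)."""

    amplitude: float
    rate_per_cm: float
    intercept: float
    rss: float
    amplitude2: float | None = None
    rate2_per_cm: float | None = None
    n_components: int = 1
    converged: bool = True

    @property
    def generations(self) -> float:
        return 100.0 * self.rate_per_cm

    def predict(self, d: np.ndarray) -> np.ndarray:
        y = self.intercept + self.amplitude * np.exp(-self.rate_per_cm * d)
        if self.n_components == 2:
            y = y + self.amplitude2 * np.exp(-self.rate2_per_cm * d)
        return y


@dataclass
class AdmixtureEvent:
    """Two-way admixture event summary for one target cluster."""

    detected: bool
    p_evidence: float
    generations: float | None = None
    generations_ci: tuple | None = None
    year_ce: float | None = None
    year_ci: tuple | None = None
    minor_proportion: float | None = None
    minor_composition: pd.Series | None = None
    major_composition: pd.Series | None = None
    date_verdict: str | None = None
    seed: int | None = None


class CurveSet:
    """Coancestry curves for all donor-group pairs of one target, holding
    the per-haplotype binned products needed for haplotype bootstraps and
    permutation nulls."""

    def __init__(self, posteriors, gmap, groups, bin_cm, min_cm, max_cm):
        post = np.asarray(posteriors, dtype=float)
        if post.ndim != 3:
            raise ValueError("posteriors must be (haplotypes, sites, groups)")
        self.posteriors = post
        # centre per site: products of deviations from the across-haplotype
        # mean field estimate the ancestry covariance directly and cancel
        # site-level (e.g. chromosome-edge) structure in the posteriors
        self.centered = post - post.mean(axis=0, keepdims=True)
        self.gmap = gmap
        self.groups = list(groups)
        H, S, G = post.shape
        if G < 2:
            raise ValueError("need at least 2 donor groups")
        self.pairs = [(a, b) for a in range(G) for b in range(a, G)]
        edges = np.arange(min_cm, max_cm + bin_cm, bin_cm)
        if len(edges) < 2:
            raise ValueError("empty bin specification")
        self.bin_edges = edges
        self.midpoints = 0.5 * (edges[:-1] + edges[1:])
        nb = len(self.midpoints)

        # per-chromosome in-range site-pair index cache
        self._chrom_pairs = []
        counts = np.zeros(nb)
        for c in gmap.chromosomes:
            sl = gmap.chrom_slice(c)
            cm = gmap.cm[sl]
            i, j = np.triu_indices(len(cm), k=1)
            d = cm[j] - cm[i]
            ok = (d >= min_cm) & (d < max_cm)
            i, j, d = i[ok], j[ok], d[ok]
            bidx = np.digitize(d, edges) - 1
            self._chrom_pairs.append((sl, i, j, bidx))
            counts += np.bincount(bidx, minlength=nb)
        if counts.sum() == 0:
            raise ValueError("no site pairs fall in the requested distance range")
        self.pair_counts = counts

        self.hap_site_sums = post.sum(axis=1)  # (H, G)
        self.n_sites = S
        q = self.centered
        n_chrom = len(self._chrom_pairs)
        self.hap_chrom_pair_sums = np.zeros((H, n_chrom, len(self.pairs), nb))
        for ci, (sl, i_loc, j_loc, bidx) in enumerate(self._chrom_pairs):
            i_idx, j_idx = sl.start + i_loc, sl.start + j_loc
            for pi, (a, b) in enumerate(self.pairs):
                prod = 0.5 * (
                    q[:, i_idx, a] * q[:, j_idx, b]
                    + q[:, i_idx, b] * q[:, j_idx, a]
                )  # (H, n_pairs_chrom)
                for h in range(H):
                    self.hap_chrom_pair_sums[h, ci, pi] += np.bincount(
                        bidx, weights=prod[h], minlength=nb
                    )
        self.hap_pair_sums = self.hap_chrom_pair_sums.sum(axis=1)

    @property
    def n_hap(self) -> int:
        return self.posteriors.shape[0]

    def _values(self, hap_idx=None) -> np.ndarray:
        """Curve values (n_pairs, n_bins) for a haplotype subset.

        The centering mean field stays the full-sample one, so subset values
        are linear in the per-haplotype sums (fast resampling).
        """
        idx = np.arange(self.n_hap) if hap_idx is None else np.asarray(hap_idx)
        sums = self.hap_pair_sums[idx].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return sums / (len(idx) * self.pair_counts)

    def mean_profile(self, hap_idx=None) -> np.ndarray:
        idx = np.arange(self.n_hap) if hap_idx is None else np.asarray(hap_idx)
        mu = self.hap_site_sums[idx].sum(axis=0)
        return mu / mu.sum()

    def curves(self, hap_idx=None) -> dict:
        vals = self._values(hap_idx)
        out = {}
        for pi, (a, b) in enumerate(self.pairs):
            key = (self.groups[a], self.groups[b])
            out[key] = CoancestryCurve(
                key, self.midpoints.copy(), vals[pi], self.pair_counts.copy()
            )
        return out

    def null_values(self, rng) -> np.ndarray:
        """Curve values under the no-ancestry-LD null: site pairs drawn from
        different haplotypes (random derangement), preserving per-site and
        per-haplotype copying composition."""
        H = self.n_hap
        perm = rng.permutation(H)
        while np.any(perm == np.arange(H)):
            perm = rng.permutation(H)
        q = self.centered
        qperm = q[perm]
        nb = len(self.midpoints)
        sums = np.zeros((len(self.pairs), nb))
        for sl, i_loc, j_loc, bidx in self._chrom_pairs:
            for pi, (a, b) in enumerate(self.pairs):
                # sum over haplotypes first, then gather the site pairs
                Wab = q[:, sl, a].T @ qperm[:, sl, b]  # (S_c, S_c)
                if a == b:
                    W = 0.5 * (Wab + Wab.T)
                else:
                    Wba = q[:, sl, b].T @ qperm[:, sl, a]
                    W = 0.5 * (Wab + Wba)
                sums[pi] += np.bincount(
                    bidx, weights=W[i_loc, j_loc], minlength=nb
                )
        with np.errstate(invalid="ignore", divide="ignore"):
            return sums / (H * self.pair_counts)


def null_site_permutation_curves(
    target_panel,
    donor_panel,
    params,
    seed: int = 0,
    bin_cm: float = 1.0,
    min_cm: float = 1.0,
    max_cm: float = 50.0,
) -> CurveSet:
    """Ancestry-LD-free reference curves for the admixture evidence test.

    Target alleles are independently permuted across haplotypes at every
    site (site frequencies kept, all within-haplotype LD destroyed), the
    pseudo-panel painted exactly like the real one, and its curves built.
    These carry the painting process's own chunk-scale autocorrelation but
    no ancestry LD, so they are the correct reference when testing for an
    admixture signal; a cross-haplotype product null alone is
    anti-conservative because it lacks the chunk component.
    """
    from .painting import site_group_posteriors
    from .panel import HaplotypePanel

    rng = np.random.default_rng(seed)
    H = target_panel.haplotypes.copy()
    for s in range(H.shape[1]):
        rng.shuffle(H[:, s])
    pseudo = HaplotypePanel(
        H, target_panel.ids, target_panel.gmap, target_panel.metadata.copy()
    )
    post, groups = site_group_posteriors(pseudo, donor_panel, params)
    return CurveSet(post, target_panel.gmap, groups, bin_cm, min_cm, max_cm)


def compute_coancestry_curves(
    posteriors: np.ndarray,
    gmap,
    groups,
    bin_cm: float = 1.0,
    min_cm: float = 1.0,
    max_cm: float = 50.0,
) -> CurveSet:
    """Build coancestry curves for every donor-group pair.

    ``posteriors`` is (haplotypes, sites, groups): per-site posterior
    copying probability per donor group from restricted painting (see
    painting.paint_panel with ``group_onehot``). Only within-chromosome
    site pairs at genetic distance in [min_cm, max_cm) contribute; the
    short-range cutoff avoids within-chunk painting artefacts.
    """
    return CurveSet(posteriors, gmap, groups, bin_cm, min_cm, max_cm)


def _linear_fit(basis: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted linear LSQ; returns (coefficients, rss)."""
    sw = np.sqrt(w)
    A = basis * sw[:, None]
    b = y * sw
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    r = A @ coef - b
    return coef, float(r @ r)


def fit_curve_exponential(curve: CoancestryCurve, n_components: int = 1) -> ExponentialFit:
    """Weighted exponential(s)-plus-intercept fit to one coancestry curve.

    Deterministic multi-start: decay rates are scanned on a fixed grid
    (1..60 per Morgan), amplitudes and intercept solved linearly at each
    grid point, and the best start polished by least squares.
    """
    ok = (curve.weights > 0) & np.isfinite(curve.values)
    d = curve.midpoints[ok]
    y = curve.values[ok]
    w = curve.weights[ok]
    if len(d) < 5:
        raise ValueError("need at least 5 non-empty bins")
    w = w / w.mean()

    if n_components == 1:
        best = None
        for lam in _RATE_GRID:
            coef, rss = _linear_fit(
                np.column_stack([np.exp(-lam * d), np.ones_like(d)]), y, w
            )
            if best is None or rss < best[0]:
                best = (rss, lam, coef)
        _, lam0, coef0 = best

        sw = np.sqrt(w)

        def resid(theta):
            A, lam, c = theta
            return sw * (c + A * np.exp(-lam * d) - y)

        def jac(theta):
            A, lam, c = theta
            e = np.exp(-lam * d)
            return np.column_stack([sw * e, -sw * A * d * e, sw])

        sol = least_squares(
            resid,
            x0=[coef0[0], lam0, coef0[1]],
            jac=jac,
            bounds=([-np.inf, 1e-6, -np.inf], [np.inf, 10.0, np.inf]),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=200,
        )
        A, lam, c = sol.x
        return ExponentialFit(
            float(A), float(lam), float(c), float(2 * sol.cost), converged=sol.success
        )

    if n_components != 2:
        raise ValueError("n_components must be 1 or 2")
    coarse = _RATE_GRID[::2]
    best = None
    for k1, l1 in enumerate(coarse):
        for l2 in coarse[k1 + 1 :]:
            basis = np.column_stack(
                [np.exp(-l1 * d), np.exp(-l2 * d), np.ones_like(d)]
            )
            coef, rss = _linear_fit(basis, y, w)
            if best is None or rss < best[0]:
                best = (rss, l1, l2, coef)
    _, l1, l2, coef = best

    sw = np.sqrt(w)

    def resid2(theta):
        A1, l1, A2, l2, c = theta
        return sw * (c + A1 * np.exp(-l1 * d) + A2 * np.exp(-l2 * d) - y)

    def jac2(theta):
        A1, l1, A2, l2, c = theta
        e1, e2 = np.exp(-l1 * d), np.exp(-l2 * d)
        return np.column_stack(
            [sw * e1, -sw * A1 * d * e1, sw * e2, -sw * A2 * d * e2, sw]
        )

    sol = least_squares(
        resid2,
        x0=[coef[0], l1, coef[1], l2, coef[2]],
        jac=jac2,
        bounds=([-np.inf, 1e-6, -np.inf, 1e-6, -np.inf], [np.inf, 10.0, np.inf, 10.0, np.inf]),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=200,
    )
    A1, l1, A2, l2, c = sol.x
    if l1 > l2:  # order rates increasing
        A1, l1, A2, l2 = A2, l2, A1, l1
    return ExponentialFit(
        float(A1),
        float(l1),
        float(c),
        float(2 * sol.cost),
        amplitude2=float(A2),
        rate2_per_cm=float(l2),
        n_components=2,
        converged=sol.success,
    )


def fit_shared_rate(
    values: np.ndarray, midpoints: np.ndarray, weights: np.ndarray, polish: bool = True
):
    """Joint fit of all pair curves with one shared decay rate.

    values (n_curves, n_bins); returns (rate_per_cm, amplitudes (n_curves,),
    intercepts, total rss).
    """
    ok = weights > 0
    d = midpoints[ok]
    w = weights[ok] / weights[ok].mean()
    Y = values[:, ok]

    def total_rss(lam):
        basis = np.column_stack([np.exp(-lam * d), np.ones_like(d)])
        tot = 0.0
        amps = np.empty(Y.shape[0])
        cons = np.empty(Y.shape[0])
        for i in range(Y.shape[0]):
            coef, rss = _linear_fit(basis, Y[i], w)
            amps[i], cons[i] = coef
            tot += rss
        return tot, amps, cons

    best = None
    for lam in _RATE_GRID:
        tot, amps, cons = total_rss(lam)
        if best is None or tot < best[0]:
            best = (tot, lam, amps, cons)
    tot, lam, amps, cons = best
    if polish:
        from scipy.optimize import minimize_scalar

        lo = max(lam - 0.02, 1e-4)
        hi = lam + 0.02
        res = minimize_scalar(
            lambda l: total_rss(l)[0], bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        if res.fun <= tot:
            lam = float(res.x)
            tot, amps, cons = total_rss(lam)
    return float(lam), amps, cons, float(tot)


def _amplitude_matrix(groups, pairs, amps) -> np.ndarray:
    G = len(groups)
    M = np.zeros((G, G))
    for (a, b), A in zip(pairs, amps):
        M[a, b] = A
        M[b, a] = A
    return M


def _decompose_event(M: np.ndarray, mu: np.ndarray, B: pd.DataFrame):
    """Resolve proportion and source compositions from the rank-one
    amplitude structure M ~ alpha(1-alpha) delta delta^T with
    mu = (1-alpha) f1 + alpha f2."""
    evals, evecs = np.linalg.eigh(M)
    k = int(np.argmax(np.abs(evals)))
    s = abs(float(evals[k]))
    v = evecs[:, k]
    Bv = B.to_numpy(dtype=float)
    # residual as a function of alpha is one-sided: below the true
    # proportion the implied minor source leaves the donor-basis simplex
    # (residual grows), above it everything fits equally well. Identify
    # alpha as the smallest value whose sources still fit (the elbow),
    # rather than the argmin of residual noise on the flat side.
    grid = []
    for alpha in np.arange(0.01, 0.501, 0.005):
        norm = np.sqrt(s / (alpha * (1 - alpha)))
        for sign in (1.0, -1.0):
            delta = sign * norm * v
            f1 = mu + alpha * delta
            f2 = mu - (1 - alpha) * delta
            beta1, r1 = _simplex_nnls(Bv.T, f1)
            beta2, r2 = _simplex_nnls(Bv.T, f2)
            grid.append((alpha, sign, r1**2 + r2**2, beta1, beta2))
    r_min = min(g[2] for g in grid)
    thresh = r_min + max(1e-8, 0.1 * r_min)
    alpha, _, _, beta1, beta2 = min(
        (g for g in grid if g[2] <= thresh), key=lambda g: g[0]
    )
    # f2 carries weight alpha; the minor side is the smaller weight
    if alpha <= 0.5:
        minor_prop, minor, major = alpha, beta2, beta1
    else:
        minor_prop, minor, major = 1 - alpha, beta1, beta2
    return (
        float(min(minor_prop, 0.5)),
        pd.Series(minor, index=B.index),
        pd.Series(major, index=B.index),
    )


def _amplitude_stat(curveset: CurveSet, vals: np.ndarray) -> float:
    """Leading eigenvalue magnitude of the amplitude matrix, with
    amplitudes evaluated as the fitted excess at the first bin: near-flat
    fits (small rate) make the raw amplitude and intercept nearly collinear
    and jointly unbounded, while the short-range excess stays stable."""
    lam, amps, _, _ = fit_shared_rate(
        vals, curveset.midpoints, curveset.pair_counts, polish=False
    )
    d0 = curveset.midpoints[curveset.pair_counts > 0][0]
    M = _amplitude_matrix(
        curveset.groups, curveset.pairs, amps * np.exp(-lam * d0)
    )
    return float(np.max(np.abs(np.linalg.eigvalsh(M))))


def infer_two_way_event(
    curveset: CurveSet,
    B: pd.DataFrame,
    evidence_threshold: float = 0.01,
    n_null: int = 100,
    seed: int = 0,
    null_curveset: CurveSet | None = None,
) -> AdmixtureEvent:
    """Detect and characterize a single two-way admixture event.

    The observed statistic is the leading amplitude-matrix eigenvalue
    magnitude from the shared-rate fit. Its null distribution comes from
    ``null_curveset`` when given (the site-permutation repaint of
    :func:`null_site_permutation_curves`, resampled over haplotypes with
    replacement n_null times) and otherwise from a cross-haplotype pairing
    permutation; p = (1 + #null >= observed) / (n_null + 1). If
    p >= threshold the event is "not detected" and the descriptive fields
    stay empty.
    """
    rng = np.random.default_rng(seed)
    vals = curveset._values()
    lam, amps, _, _ = fit_shared_rate(vals, curveset.midpoints, curveset.pair_counts)
    obs_stat = _amplitude_stat(curveset, vals)
    exceed = 0
    for _ in range(n_null):
        if null_curveset is not None:
            idx = rng.integers(0, null_curveset.n_hap, size=null_curveset.n_hap)
            nstat = _amplitude_stat(null_curveset, null_curveset._values(idx))
        else:
            nstat = _amplitude_stat(curveset, curveset.null_values(rng))
        if nstat >= obs_stat:
            exceed += 1
    p = (1 + exceed) / (n_null + 1)
    if p >= evidence_threshold:
        return AdmixtureEvent(detected=False, p_evidence=p, seed=seed)

    mu = curveset.mean_profile()
    M = _amplitude_matrix(curveset.groups, curveset.pairs, amps)
    minor_prop, minor, major = _decompose_event(M, mu, B)
    g = 100.0 * lam
    return AdmixtureEvent(
        detected=True,
        p_evidence=p,
        generations=g,
        year_ce=generations_to_year(g),
        minor_proportion=minor_prop,
        minor_composition=minor,
        major_composition=major,
        seed=seed,
    )


def compare_one_vs_two_dates(
    curves: dict,
    designated_groups: list | None = None,
    n_sim: int = 100,
    seed: int = 0,
    p_threshold: float = 0.05,
) -> tuple[str, pd.DataFrame]:
    """Per-curve one- vs two-date comparison with a parametric bootstrap.

    For each curve the RSS reduction of the two-exponential fit over the
    one-exponential fit is compared with its distribution under data
    simulated from the one-exponential fit plus Gaussian bin noise. A curve
    with no significant decay at all is labelled "no-decay". The overall
    verdict is "two-date" only if some curve (restricted to pairs involving
    ``designated_groups``, when given) prefers two dates; "no admixture"
    when no curve shows decay.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for key, curve in curves.items():
        ok = (curve.weights > 0) & np.isfinite(curve.values)
        d = curve.midpoints[ok]
        y = curve.values[ok]
        w = curve.weights[ok] / curve.weights[ok].mean()
        fit1 = fit_curve_exponential(curve, 1)
        fit2 = fit_curve_exponential(curve, 2)
        # decay evidence: flat model vs one exponential
        coef0, rss0 = _linear_fit(np.ones((len(d), 1)), y, w)
        dof0 = max(len(d) - 1, 1)
        sigma0 = np.sqrt(rss0 / dof0)
        stat_decay = rss0 - fit1.rss
        stat_two = fit1.rss - fit2.rss
        sigma1 = np.sqrt(max(fit1.rss, 1e-300) / max(len(d) - 3, 1))
        exceed_decay = 0
        exceed_two = 0
        sw = np.sqrt(w)
        for _ in range(n_sim):
            y0 = coef0[0] + sigma0 * rng.standard_normal(len(d)) / sw
            c_dummy = CoancestryCurve(key, d, y0, curve.weights[ok])
            f1n = fit_curve_exponential(c_dummy, 1)
            _, r0n = _linear_fit(np.ones((len(d), 1)), y0, w)
            if r0n - f1n.rss >= stat_decay:
                exceed_decay += 1
            y1 = fit1.predict(d) + sigma1 * rng.standard_normal(len(d)) / sw
            c1_dummy = CoancestryCurve(key, d, y1, curve.weights[ok])
            f1b = fit_curve_exponential(c1_dummy, 1)
            f2b = fit_curve_exponential(c1_dummy, 2)
            if f1b.rss - f2b.rss >= stat_two:
                exceed_two += 1
        p_decay = (1 + exceed_decay) / (n_sim + 1)
        p_two = (1 + exceed_two) / (n_sim + 1)
        if p_decay >= p_threshold:
            verdict = "no-decay"
        elif p_two < p_threshold:
            verdict = "two-date"
        else:
            verdict = "one-date"
        rows.append(
            {
                "pair": key,
                "p_decay": p_decay,
                "p_two_date": p_two,
                "verdict": verdict,
                "rate1": fit1.rate_per_cm,
                "rate2a": fit2.rate_per_cm,
                "rate2b": fit2.rate2_per_cm,
            }
        )
    table = pd.DataFrame(rows)
    if (table["verdict"] == "no-decay").all():
        overall = "no admixture"
    else:
        considered = table
        if designated_groups is not None:
            mask = table["pair"].apply(
                lambda p: any(g in p for g in designated_groups)
            )
            considered = table[mask]
        overall = (
            "two-date" if (considered["verdict"] == "two-date").any() else "one-date"
        )
    return overall, table


def bootstrap_event_ci(
    curveset: CurveSet,
    n_boot: int = 50,
    seed: int = 0,
    by_individual: bool = True,
) -> dict:
    """95% bootstrap interval for the admixture date.

    With ``by_individual`` each resample builds pseudo-haplotypes that take
    a random target haplotype's painting per chromosome (resampling both
    the individual and chromosome axes, the pseudo-individual construct of
    the profiles bootstrap); otherwise haplotypes are resampled whole. The
    shared-rate fit is repeated per resample and the 2.5%/97.5% quantiles
    of g (and their calendar conversion) reported. Degenerate resamples
    (fit failure) are skipped and counted.
    """
    rng = np.random.default_rng(seed)
    H = curveset.n_hap
    n_chrom = curveset.hap_chrom_pair_sums.shape[1]
    gs = []
    skipped = 0
    for _ in range(n_boot):
        if by_individual and H % 2 == 0 and n_chrom >= 2:
            # pseudo-individual resampling: each of H pseudo-haplotypes takes
            # a random member's painting per chromosome, preserving
            # within-chromosome correlation while resampling both the
            # individual and chromosome axes
            picks = rng.integers(0, H, size=(H, n_chrom))
            sums = curveset.hap_chrom_pair_sums[
                picks, np.arange(n_chrom)[None, :]
            ].sum(axis=(0, 1))
            with np.errstate(invalid="ignore", divide="ignore"):
                vals = sums / (H * curveset.pair_counts)
        else:
            idx = rng.integers(0, H, size=H)
            vals = curveset._values(idx)
        try:
            lam, _, _, _ = fit_shared_rate(
                vals, curveset.midpoints, curveset.pair_counts, polish=False
            )
            gs.append(100.0 * lam)
        except (ValueError, np.linalg.LinAlgError):
            skipped += 1
    gs = np.array(gs)
    lo, hi = np.quantile(gs, [0.025, 0.975])
    return {
        "g_samples": gs,
        "g_ci": (float(lo), float(hi)),
        "year_ci": (generations_to_year(hi), generations_to_year(lo)),
        "n_skipped": skipped,
    }


def generations_to_year(
    g: float, generation_time: float = 28.0, reference_year: float = 1940.0
) -> float:
    """Calendar year CE of an event g generations before the reference."""
    if g < 0:
        raise ValueError("g must be >= 0")
    return reference_year - generation_time * g


def year_to_generations(
    year: float, generation_time: float = 28.0, reference_year: float = 1940.0
) -> float:
    """Inverse of :func:`generations_to_year`."""
    g = (reference_year - year) / generation_time
    if g < 0:
        raise ValueError("year is after the reference year")
    return g
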