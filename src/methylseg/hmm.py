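"""Two-state HMM segmentation of a methylome into methylated regions.

The genome of one strain is modelled as an alternating sequence of LOW
and HIGH methylation states.  Emissions are beta-binomial read counts
with separate parameters per state and sequence context (six
distributions in total), so that the sparse CHH, intermediate CHG and
bimodal CG rate distributions each inform the segmentation on their own
scale.  Parameters are learned by Baum-Welch; cytosines are then
classified by posterior decoding, consecutive HIGH stretches are scored
by the sum of their methylation rates, and scores are tested against an
empirical null obtained by permuting all cytosines across the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .betabinom import BetaBinomParams, betabinom_logpmf, fit_betabinom_mle
from .fdr import storey_qvalues
from .io import CONTEXTS, MethylomeTable

LOW, HIGH = 0, 1


@dataclass
class HmmModel:
    """Two-state HMM with per-(state, context) beta-binomial emissions."""

    transition: np.ndarray  # 2x2 row-stochastic
    start: np.ndarray  # length 2
    emissions: dict  # (state, context) -> BetaBinomParams
    log_likelihoods: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.start = np.asarray(self.start, dtype=float)
        if self.transition.shape != (2, 2) or not np.allclose(
            self.transition.sum(axis=1), 1.0
        ):
            raise ValueError("transition must be a 2x2 stochastic matrix")
        if len(self.emissions) != 6:
            raise ValueError("need 6 emission distributions (2 states x 3 contexts)")


@dataclass
class MethylatedRegion:
    """A scored HIGH-state genome segment (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    score: float
    n_cytosines: int
    p_value: float = float("nan")
    q_value: float = float("nan")

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must be <= end")
        if self.score < 0:
            raise ValueError("score must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# observation preparation

def _chains(table: MethylomeTable):
    """Split a table into per-chromosome observation arrays."""
    df = table.df
    ctx_idx = df["context"].map({c: i for i, c in enumerate(CONTEXTS)}).to_numpy()
    chains = []
    for chrom, sub in df.groupby("chrom", sort=True):
        idx = sub.index.to_numpy()
        chains.append(
            dict(
                chrom=chrom,
                pos=sub["pos"].to_numpy(int),
                ctx=ctx_idx[idx],
                x=sub["meth_reads"].to_numpy(float),
                n=sub["total_reads"].to_numpy(float),
            )
        )
    return chains


def _emission_logprob(chain, emissions) -> np.ndarray:
    """T x 2 matrix of per-position emission log-probabilities."""
    T = len(chain["pos"])
    logb = np.zeros((T, 2))
    for s in (LOW, HIGH):
        for ci, ctx in enumerate(CONTEXTS):
            mask = chain["ctx"] == ci
            if not np.any(mask):
                continue
            par = emissions[(s, ctx)]
            logb[mask, s] = betabinom_logpmf(
                chain["x"][mask], chain["n"][mask], par.alpha, par.beta
            )
    return logb


# ---------------------------------------------------------------------------
# forward-backward (scaled)

def _forward_backward(logb: np.ndarray, transition: np.ndarray, start: np.ndarray):
    """Scaled forward-backward pass.

    Returns (gamma, xi_sum, loglik): posterior state probabilities
    (T x 2), expected transition counts summed over time (2 x 2), and
    the total log-likelihood of the chain.
    """
    T = logb.shape[0]
    b = np.exp(logb - logb.max(axis=1, keepdims=True))
    shift = logb.max(axis=1)
    alpha = np.empty((T, 2))
    c = np.empty(T)
    alpha[0] = start * b[0]
    c[0] = alpha[0].sum()
    alpha[0] /= c[0]
    for t in range(1, T):
        alpha[t] = (alpha[t - 1] @ transition) * b[t]
        c[t] = alpha[t].sum()
        alpha[t] /= c[t]
    beta = np.empty((T, 2))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (transition @ (b[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi_sum = np.zeros((2, 2))
    for t in range(T - 1):
        xi = (
            alpha[t][:, None]
            * transition
            * (b[t + 1] * beta[t + 1])[None, :]
            / c[t + 1]
        )
        xi_sum += xi / xi.sum()
    loglik = float(np.sum(np.log(c)) + np.sum(shift))
    return gamma, xi_sum, loglik


# ---------------------------------------------------------------------------
# Baum-Welch training

def default_initial_model() -> HmmModel:
    """Symmetry-breaking starting point: sparse LOW vs methylated HIGH."""
    emissions = {}
    for ctx in CONTEXTS:
        emissions[(LOW, ctx)] = BetaBinomParams(0.25, 4.75)  # mu 0.05
        emissions[(HIGH, ctx)] = BetaBinomParams(3.5, 1.5)  # mu 0.7
    return HmmModel(
        transition=np.array([[0.99, 0.01], [0.01, 0.99]]),
        start=np.array([0.5, 0.5]),
        emissions=emissions,
    )


def baum_welch(
    table: MethylomeTable,
    max_iter: int = 30,
    tol: float = 1e-4,
    initial: HmmModel | None = None,
) -> HmmModel:
    """Train the segmentation HMM on one strain's methylome.

    Runs at most ``max_iter`` EM iterations, stopping early when the
    relative change in total log-likelihood drops below ``tol``.  One
    model is fitted genome-wide; chromosomes are independent chains
    sharing parameters.  After training, states are relabelled if needed
    so that HIGH has the larger mean methylation rate in every context.
    """
    if len(table) == 0:
        raise ValueError("empty methylome table")
    chains = _chains(table)
    covered = table.df["total_reads"] > 0
    rates = (
        table.df.loc[covered, "meth_reads"] / table.df.loc[covered, "total_reads"]
    )
    if rates.nunique() < 2:
        raise ValueError("degenerate input: fewer than 2 distinct methylation rates")

    model = initial if initial is not None else default_initial_model()
    transition = model.transition.copy()
    start = model.start.copy()
    emissions = dict(model.emissions)
    logliks: list = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        gammas, xi_total, ll_total = [], np.zeros((2, 2)), 0.0
        start_acc = np.zeros(2)
        for chain in chains:
            logb = _emission_logprob(chain, emissions)
            gamma, xi_sum, ll = _forward_backward(logb, transition, start)
            gammas.append(gamma)
            xi_total += xi_sum
            ll_total += ll
            start_acc += gamma[0]
        logliks.append(ll_total)

        # M-step: transitions and start distribution
        row = xi_total.sum(axis=1, keepdims=True)
        if np.all(row > 0):
            transition = xi_total / row
        start = start_acc / start_acc.sum()

        # M-step: emission distributions, weighted by state posteriors
        for s in (LOW, HIGH):
            for ci, ctx in enumerate(CONTEXTS):
                xs, ns, ws = [], [], []
                for chain, gamma in zip(chains, gammas):
                    mask = (chain["ctx"] == ci) & (chain["n"] > 0)
                    xs.append(chain["x"][mask])
                    ns.append(chain["n"][mask])
                    ws.append(gamma[mask, s])
                x = np.concatenate(xs)
                n = np.concatenate(ns)
                w = np.concatenate(ws)
                if x.size == 0 or w.sum() <= 1e-8:
                    continue  # keep previous parameters
                emissions[(s, ctx)] = fit_betabinom_mle(
                    np.column_stack([x, n]), weights=w
                )

        if len(logliks) >= 2:
            prev, cur = logliks[-2], logliks[-1]
            if abs(cur - prev) / (abs(prev) + 1e-12) < tol:
                converged = True
                break

    # state identifiability: HIGH must be the more methylated state
    mean_mu = [np.mean([emissions[(s, c)].mu for c in CONTEXTS]) for s in (LOW, HIGH)]
    if mean_mu[LOW] > mean_mu[HIGH]:
        emissions = {
            (1 - s, c): p for (s, c), p in emissions.items()
        }
        transition = transition[::-1, ::-1].copy()
        start = start[::-1].copy()

    return HmmModel(
        transition=transition,
        start=start,
        emissions=emissions,
        log_likelihoods=logliks,
        n_iter=it,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# posterior decoding

def posterior_decode(model: HmmModel, table: MethylomeTable):
    """Posterior HIGH-state probability and argmax path per position.

    Returns (posterior_high, path) as arrays aligned with ``table.df``.
    """
    post = np.empty(len(table))
    path = np.empty(len(table), dtype=int)
    offset = 0
    for chain in _chains(table):
        T = len(chain["pos"])
        logb = _emission_logprob(chain, model.emissions)
        gamma, _, _ = _forward_backward(logb, model.transition, model.start)
        post[offset : offset + T] = gamma[:, HIGH]
        path[offset : offset + T] = (gamma[:, HIGH] >= 0.5).astype(int)
        offset += T
    return post, path


# ---------------------------------------------------------------------------
# segmentation, scoring, permutation FDR, trimming

MAX_UNCOVERED_GAP = 50  # bp without a covered cytosine that ends a segment


def segment_and_score(path: np.ndarray, table: MethylomeTable):
    """Candidate regions from maximal HIGH runs of the decoded path.

    A run is split wherever at least ``MAX_UNCOVERED_GAP`` bp pass
    without a covered cytosine.  Region boundaries are the first and
    last covered cytosines of each piece; the score is the sum of the
    contained methylation rates.
    """
    df = table.df
    chroms = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy(int)
    n = df["total_reads"].to_numpy(float)
    x = df["meth_reads"].to_numpy(float)
    regions = []
    i, T = 0, len(df)
    while i < T:
        if path[i] != HIGH:
            i += 1
            continue
        j = i
        while j + 1 < T and path[j + 1] == HIGH and chroms[j + 1] == chroms[i]:
            j += 1
        # split the run [i, j] at uncovered gaps >= MAX_UNCOVERED_GAP bp
        cov_idx = [k for k in range(i, j + 1) if n[k] > 0]
        if cov_idx:
            piece = [cov_idx[0]]
            pieces = []
            for k in cov_idx[1:]:
                if pos[k] - pos[piece[-1]] - 1 >= MAX_UNCOVERED_GAP:
                    pieces.append(piece)
                    piece = [k]
                else:
                    piece.append(k)
            pieces.append(piece)
            for piece in pieces:
                idx = np.array(piece)
                score = float(np.sum(x[idx] / n[idx]))
                regions.append(
                    MethylatedRegion(
                        chrom=str(chroms[i]),
                        start=int(pos[idx[0]]),
                        end=int(pos[idx[-1]]),
                        score=score,
                        n_cytosines=len(piece),
                    )
                )
        i = j + 1
    return regions


def permutation_fdr(
    candidates,
    table: MethylomeTable,
    model: HmmModel,
    n_perm: int = 100,
    alpha_fdr: float = 0.05,
    rng: np.random.Generator | None = None,
):
    """Empirical score test against genome-wide cytosine permutations.

    The cytosine observations (context and read counts) are shuffled
    across the position grid, the permuted genome is decoded with the
    trained model and segmented, and all permuted segment scores are
    pooled into the null distribution.  Each candidate's p-value is
    ``(1 + #null >= score) / (1 + #null)``; survivors of Storey FDR at
    ``alpha_fdr`` are the methylated regions.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    if not candidates:
        return []
    null_scores = []
    df = table.df
    for _ in range(n_perm):
        perm = rng.permutation(len(df))
        shuffled = df.copy()
        shuffled[["context", "meth_reads", "total_reads"]] = (
            df[["context", "meth_reads", "total_reads"]].to_numpy()[perm]
        )
        ptable = MethylomeTable(shuffled, table.sample_id, table.replicate_id)
        _, path = posterior_decode(model, ptable)
        null_scores.extend(r.score for r in segment_and_score(path, ptable))
    null = np.sort(np.asarray(null_scores))
    m = null.size
    out = []
    scores = np.array([r.score for r in candidates])
    p = (1.0 + m - np.searchsorted(null, scores, side="left")) / (1.0 + m)
    q = storey_qvalues(p)
    for r, pv, qv in zip(candidates, p, q):
        if qv < alpha_fdr:
            out.append(replace(r, p_value=float(pv), q_value=float(qv)))
    return out


LOW_RATE_TRIM = 0.10  # boundary positions below this rate are trimmed off


def trim_boundaries(region: MethylatedRegion, table: MethylomeTable):
    """Strip low-rate positions from region boundaries.

    Leading and trailing covered cytosines with methylation rate below
    10% are reassigned to the flanking low-methylation space, up to the
    first position exceeding 10%.  Returns the trimmed region, or None
    when nothing remains.  Idempotent.
    """
    df = table.df
    sub = df[
        (df["chrom"] == region.chrom)
        & (df["pos"] >= region.start)
        & (df["pos"] <= region.end)
        & (df["total_reads"] > 0)
    ]
    if sub.empty:
        return None
    rates = (sub["meth_reads"] / sub["total_reads"]).to_numpy()
    pos = sub["pos"].to_numpy(int)
    lo, hi = 0, len(rates) - 1
    while lo <= hi and rates[lo] < LOW_RATE_TRIM:
        lo += 1
    while hi >= lo and rates[hi] < LOW_RATE_TRIM:
        hi -= 1
    if lo > hi:
        return None
    return replace(
        region,
        start=int(pos[lo]),
        end=int(pos[hi]),
        score=float(np.sum(rates[lo : hi + 1])),
        n_cytosines=int(hi - lo + 1),
    )


# ---------------------------------------------------------------------------
# convenience pipeline

def call_mrs(
    table: MethylomeTable,
    max_iter: int = 30,
    n_perm: int = 100,
    alpha_fdr: float = 0.05,
    rng: np.random.Generator | None = None,
    initial: HmmModel | None = None,
):
    """Full per-strain MR calling: train, decode, segment, test, trim."""
    model = baum_welch(table, max_iter=max_iter, initial=initial)
    _, path = posterior_decode(model, table)
    candidates = segment_and_score(path, table)
    regions = permutation_fdr(
        candidates, table, model, n_perm=n_perm, alpha_fdr=alpha_fdr, rng=rng
    )
    trimmed = []
    for r in regions:
        t = trim_boundaries(r, table)
        if t is not None:
            trimmed.append(t)
    return trimmed, model
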