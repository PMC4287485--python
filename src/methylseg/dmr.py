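"""Differentially methylated region (DMR) calling across strains.

Candidate segments are built from the breakpoints of the per-strain
methylated regions.  Each admissible strain pair is tested with a
beta-binomial likelihood-ratio test: three context-specific
distributions fitted per strain versus three common distributions, the
doubled log-likelihood ratio referred to chi-squared with 6 degrees of
freedom.  Significant pairs define the edges of a per-region graph
whose vertices are strains; the minimum vertex coloring of that graph
groups strains into epialleles, tie-broken by the lowest grouping
diversity.  Groups are re-tested with the same machinery, overlapping
DMRs are resolved by diversity, and DMRs passing length, fold-change
and minimum-rate filters are classified as highly differentially
methylated regions (hDMRs).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .betabinom import BetaBinomParams, fit_betabinom_mle, loglik
from .fdr import storey_qvalues
from .io import CONTEXTS, SamplePool


# ---------------------------------------------------------------------------
# per-strain count access

class StrainData:
    """Fast per-segment count extraction for one accession.

    Replicates contribute as independent observations to likelihoods;
    coverage summaries use replicate-accumulated counts.
    """

    def __init__(self, pool: SamplePool):
        self.accession_id = pool.accession_id
        self._rep = {}  # chrom -> (pos, ctx, x, n) over all replicate rows
        self._acc = {}  # chrom -> (pos, ctx, x, n) accumulated
        ctx_map = {c: i for i, c in enumerate(CONTEXTS)}
        rows = []
        for rep in pool.replicates:
            df = rep.df
            rows.append(df)
        import pandas as pd

        allrows = pd.concat(rows, ignore_index=True)
        allrows = allrows.sort_values(["chrom", "pos"], kind="stable")
        for chrom, sub in allrows.groupby("chrom", sort=True):
            self._rep[chrom] = (
                sub["pos"].to_numpy(int),
                sub["context"].map(ctx_map).to_numpy(int),
                sub["meth_reads"].to_numpy(float),
                sub["total_reads"].to_numpy(float),
            )
        acc = pool.accumulated().sort_values(["chrom", "pos"], kind="stable")
        for chrom, sub in acc.groupby("chrom", sort=True):
            self._acc[chrom] = (
                sub["pos"].to_numpy(int),
                sub["context"].map(ctx_map).to_numpy(int),
                sub["meth_reads"].to_numpy(float),
                sub["total_reads"].to_numpy(float),
            )

    def _slice(self, store, chrom, start, end):
        if chrom not in store:
            return None
        pos, ctx, x, n = store[chrom]
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="right")
        return pos[lo:hi], ctx[lo:hi], x[lo:hi], n[lo:hi]

    def counts(self, chrom, start, end):
        """Replicate-level (x, n) arrays per context, covered positions only."""
        sl = self._slice(self._rep, chrom, start, end)
        out = {}
        if sl is None:
            return out
        _, ctx, x, n = sl
        for ci, c in enumerate(CONTEXTS):
            mask = (ctx == ci) & (n > 0)
            if np.any(mask):
                out[c] = (x[mask], n[mask])
        return out

    def n_covered(self, chrom, start, end, min_cov: int = 3) -> int:
        """Number of positions with accumulated coverage >= min_cov."""
        sl = self._slice(self._acc, chrom, start, end)
        if sl is None:
            return 0
        _, _, _, n = sl
        return int(np.sum(n >= min_cov))

    def context_rates(self, chrom, start, end):
        """Accumulated (meth, total, n_sites) per context in the segment."""
        sl = self._slice(self._acc, chrom, start, end)
        out = {}
        if sl is None:
            return out
        _, ctx, x, n = sl
        for ci, c in enumerate(CONTEXTS):
            mask = (ctx == ci) & (n > 0)
            out[c] = (float(x[mask].sum()), float(n[mask].sum()), int(mask.sum()))
        return out


# ---------------------------------------------------------------------------
# candidate construction

@dataclass
class CandidateSegment:
    chrom: str
    start: int
    end: int
    high_strains: frozenset  # HIGH state throughout the segment
    overlapping_strains: frozenset  # any MR overlap (mixed or full)
    covered_counts: dict = field(default_factory=dict)  # strain -> n covered sites
    admissible_strains: frozenset = frozenset()
    admissible_pairs: tuple = ()

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _components(intervals):
    """Connected components of overlapping (start, end) intervals."""
    order = sorted(range(len(intervals)), key=lambda i: intervals[i][:2])
    comps, cur, cur_end = [], [], None
    for i in order:
        s, e = intervals[i][0], intervals[i][1]
        if cur and s <= cur_end:
            cur.append(i)
            cur_end = max(cur_end, e)
        else:
            if cur:
                comps.append(cur)
            cur, cur_end = [i], e
    if cur:
        comps.append(cur)
    return comps


def build_candidates(mrs_by_strain: dict) -> list:
    """Candidate segments from MR breakpoints.

    Within each connected component of overlapping MRs (across all
    strains), every pair of breakpoint coordinates defines a segment; a
    segment is kept when at least one strain is in HIGH state across
    its whole extent.  Whole MRs shared by several strains are included
    by construction (their own endpoints are breakpoints).
    """
    if len(mrs_by_strain) < 2:
        raise ValueError("need at least 2 strains")
    by_chrom: dict = {}
    for strain, mrs in mrs_by_strain.items():
        for mr in mrs:
            by_chrom.setdefault(mr.chrom, []).append((mr.start, mr.end, strain))
    candidates = []
    for chrom in sorted(by_chrom):
        ivs = by_chrom[chrom]
        for comp in _components(ivs):
            comp_ivs = [ivs[i] for i in comp]
            bps = sorted({c for s, e, _ in comp_ivs for c in (s, e)})
            for a, b in itertools.combinations(bps, 2):
                high = frozenset(
                    st for s, e, st in comp_ivs if s <= a and e >= b
                )
                if not high:
                    continue
                overlapping = frozenset(
                    st for s, e, st in comp_ivs if s <= b and e >= a
                )
                candidates.append(
                    CandidateSegment(chrom, a, b, high, overlapping)
                )
    candidates.sort(key=lambda c: (c.chrom, c.start, c.end))
    return candidates


def _reciprocal_overlap(a, b) -> float:
    """Smaller of the two mutual overlap fractions of intervals a, b."""
    inter = min(a[2], b[2]) - max(a[1], b[1]) + 1
    if a[0] != b[0] or inter <= 0:
        return 0.0
    return min(inter / (a[2] - a[1] + 1), inter / (b[2] - b[1] + 1))


def filter_candidates(
    candidates,
    strain_data: dict,
    min_sites: int = 10,
    min_cov: int = 3,
    max_reciprocal: float = 0.70,
) -> list:
    """Apply the candidate filters and schedule admissible pairs.

    (a) a region must have >= 2 strains with at least ``min_sites``
        cytosines covered by >= ``min_cov`` accumulated reads;
    (b) a region reciprocally overlapping a previously accepted region
        by >= ``max_reciprocal`` is discarded (greedy, genome order);
    (c) a pair is not tested when both strains are in LOW state
        throughout the region;
    (d) strains with fewer than half the maximum per-strain covered-site
        count in the region are excluded.
    """
    accepted = []
    kept_spans = []
    for cand in candidates:
        counts = {
            s: sd.n_covered(cand.chrom, cand.start, cand.end, min_cov)
            for s, sd in strain_data.items()
        }
        cand.covered_counts = counts
        eligible = {s for s, c in counts.items() if c >= min_sites}
        if len(eligible) < 2:
            continue
        span = (cand.chrom, cand.start, cand.end)
        if any(_reciprocal_overlap(span, k) >= max_reciprocal for k in kept_spans):
            continue
        max_count = max(counts.values())
        admissible = frozenset(
            s for s in eligible if counts[s] >= max_count / 2.0
        )
        pairs = []
        for s1, s2 in itertools.combinations(sorted(admissible), 2):
            both_low = (
                s1 not in cand.overlapping_strains
                and s2 not in cand.overlapping_strains
            )
            if both_low:
                continue
            pairs.append((s1, s2))
        if not pairs:
            continue
        cand.admissible_strains = admissible
        cand.admissible_pairs = tuple(pairs)
        accepted.append(cand)
        kept_spans.append(span)
    return accepted


# ---------------------------------------------------------------------------
# pairwise likelihood-ratio test

@dataclass
class PairwiseDmrTest:
    chrom: str
    start: int
    end: int
    strain_a: str
    strain_b: str
    lr: float
    df: int
    p_value: float
    prefilter_pass: bool
    q_value: float = float("nan")
    params_a: dict = field(default_factory=dict)  # context -> BetaBinomParams
    params_b: dict = field(default_factory=dict)
    params_common: dict = field(default_factory=dict)
    per_context_p: dict = field(default_factory=dict)


def _pooled_params(counts: dict) -> BetaBinomParams | None:
    """Fit one beta-binomial to counts accumulated over all contexts."""
    xs = [x for x, _ in counts.values()]
    ns = [n for _, n in counts.values()]
    if not xs:
        return None
    x = np.concatenate(xs)
    n = np.concatenate(ns)
    if x.size == 0:
        return None
    return fit_betabinom_mle(np.column_stack([x, n]))


def lrt_pairwise(
    chrom: str,
    start: int,
    end: int,
    strain_a: str,
    strain_b: str,
    counts_a: dict,
    counts_b: dict,
) -> PairwiseDmrTest:
    """Beta-binomial likelihood-ratio test between two strains.

    ``counts_a``/``counts_b`` map context -> (meth, total) arrays with
    one entry per replicate observation.  Contexts without data in
    either strain contribute nothing and reduce the degrees of freedom
    by two.  The mean +/- 2 sd prefilter is evaluated on parameters
    fitted to counts accumulated over all contexts.
    """
    lr_total = 0.0
    df = 0
    params_a, params_b, params_common, per_ctx_p = {}, {}, {}, {}
    for ctx in CONTEXTS:
        has_a = ctx in counts_a
        has_b = ctx in counts_b
        if not has_a and not has_b:
            continue
        df += 2
        xa, na = counts_a.get(ctx, (np.empty(0), np.empty(0)))
        xb, nb = counts_b.get(ctx, (np.empty(0), np.empty(0)))
        xc = np.concatenate([xa, xb])
        nc = np.concatenate([na, nb])
        pc = fit_betabinom_mle(np.column_stack([xc, nc]))
        params_common[ctx] = pc
        ll_c = loglik(xc, nc, pc.alpha, pc.beta)
        ll_s = 0.0
        if has_a:
            pa = fit_betabinom_mle(np.column_stack([xa, na]))
            params_a[ctx] = pa
            ll_s += loglik(xa, na, pa.alpha, pa.beta)
        if has_b:
            pb = fit_betabinom_mle(np.column_stack([xb, nb]))
            params_b[ctx] = pb
            ll_s += loglik(xb, nb, pb.alpha, pb.beta)
        lr_ctx = max(0.0, 2.0 * (ll_s - ll_c))
        per_ctx_p[ctx] = float(stats.chi2.sf(lr_ctx, 2))
        lr_total += lr_ctx
    if df == 0:
        raise ValueError("no context with data in either strain")
    p = float(stats.chi2.sf(lr_total, df))

    pa_all = _pooled_params(counts_a)
    pb_all = _pooled_params(counts_b)
    if pa_all is None or pb_all is None:
        prefilter = False
    else:
        lo_a, hi_a = pa_all.mu - 2 * pa_all.sigma, pa_all.mu + 2 * pa_all.sigma
        lo_b, hi_b = pb_all.mu - 2 * pb_all.sigma, pb_all.mu + 2 * pb_all.sigma
        prefilter = hi_a < lo_b or hi_b < lo_a
    return PairwiseDmrTest(
        chrom, start, end, strain_a, strain_b,
        lr=float(lr_total), df=df, p_value=p, prefilter_pass=prefilter,
        params_a=params_a, params_b=params_b, params_common=params_common,
        per_context_p=per_ctx_p,
    )


# ---------------------------------------------------------------------------
# strain grouping by vertex coloring

@dataclass
class StrainGrouping:
    assignment: dict  # strain -> group index
    group_means: dict  # group -> np.ndarray over contexts (nan where absent)
    grouping_diversity: float
    n_groups: int


MAX_EXACT_COLORING_VERTICES = 16
_MAX_COLORINGS = 20000


def _enumerate_colorings(order, adj, k):
    """All proper k-colorings (canonical first-use color order), capped."""
    n = len(order)
    results = []

    def backtrack(i, colors, used):
        if len(results) >= _MAX_COLORINGS:
            return
        if i == n:
            results.append(dict(colors))
            return
        v = order[i]
        limit = min(used + 1, k)
        for c in range(limit):
            if any(colors.get(u) == c for u in adj[v]):
                continue
            colors[v] = c
            backtrack(i + 1, colors, max(used, c + 1))
            del colors[v]

    backtrack(0, {}, 0)
    return results


def _diversity(assignment, strain_means):
    """Mean accumulated |strain mean - group mean| over assigned strains."""
    groups: dict = {}
    for s, g in assignment.items():
        groups.setdefault(g, []).append(s)
    gmeans = {}
    for g, members in groups.items():
        stacked = np.vstack([strain_means[s] for s in members])
        ok = ~np.isnan(stacked)
        counts = ok.sum(axis=0)
        sums = np.where(ok, stacked, 0.0).sum(axis=0)
        gmeans[g] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    total = 0.0
    n = 0
    for s, g in assignment.items():
        diff = np.abs(strain_means[s] - gmeans[g])
        total += float(np.nansum(diff))
        n += 1
    return (total / n if n else 0.0), gmeans


def group_strains(strains, edges, strain_means: dict) -> StrainGrouping:
    """Group strains into epialleles by minimum vertex coloring.

    ``edges`` are unordered significant strain pairs; ``strain_means``
    maps strain -> array of per-context mean methylation rates (nan for
    contexts without data).  Connected vertices are colored exactly
    (iterative deepening from two colors, processing vertices in
    descending degree order); among minimum colorings the one with the
    lowest grouping diversity wins.  Strains without any edge join the
    group whose mean profile is nearest.
    """
    strains = sorted(strains)
    adj = {s: set() for s in strains}
    for a, b in edges:
        if a == b:
            raise ValueError("self-loop in DMR graph")
        adj[a].add(b)
        adj[b].add(a)
    connected = [s for s in strains if adj[s]]
    isolated = [s for s in strains if not adj[s]]

    if not connected:
        assignment = {s: 0 for s in strains}
        div, gmeans = _diversity(assignment, strain_means)
        return StrainGrouping(assignment, gmeans, div, 1)

    order = sorted(connected, key=lambda s: (-len(adj[s]), s))
    if len(connected) > MAX_EXACT_COLORING_VERTICES:
        # greedy fallback: first non-colliding color in degree order
        assignment = {}
        for v in order:
            used = {assignment[u] for u in adj[v] if u in assignment}
            c = 0
            while c in used:
                c += 1
            assignment[v] = c
    else:
        assignment = None
        for k in range(2, len(connected) + 1):
            colorings = _enumerate_colorings(order, adj, k)
            if colorings:
                best, best_div = None, np.inf
                for col in colorings:
                    div, _ = _diversity(col, strain_means)
                    if div < best_div:
                        best, best_div = col, div
                assignment = best
                break
        assert assignment is not None

    # assign isolated strains to the nearest group by accumulated |diff|
    _, gmeans = _diversity(assignment, strain_means)
    for s in isolated:
        best_g, best_d = None, np.inf
        for g, gm in gmeans.items():
            d = float(np.nansum(np.abs(strain_means[s] - gm)))
            if d < best_d:
                best_g, best_d = g, d
        assignment[s] = best_g
    div, gmeans = _diversity(assignment, strain_means)
    n_groups = len(set(assignment.values()))
    return StrainGrouping(dict(assignment), gmeans, float(div), n_groups)


# ---------------------------------------------------------------------------
# group-level test, overlap resolution, hDMR classification

@dataclass
class Dmr:
    chrom: str
    start: int
    end: int
    grouping: StrainGrouping
    lr: float
    df: int
    p_value: float
    q_value: float = float("nan")
    per_context_p: dict = field(default_factory=dict)
    significant_contexts: tuple = ()
    group_rates: dict = field(default_factory=dict)  # group -> ctx -> (meth, total, n_sites)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def grouping_diversity(self) -> float:
        return self.grouping.grouping_diversity


@dataclass
class HDmr:
    dmr: Dmr
    fold_change: float
    best_context: str
    max_group_rate: float


def group_level_test(chrom, start, end, grouping: StrainGrouping,
                     counts_by_strain: dict) -> Dmr:
    """Pairwise-test machinery applied to strain groups.

    Read counts of all strains in a group are treated as replicate
    observations of that group.  For g groups the likelihood ratio is
    referred to chi-squared with 6(g-1) degrees of freedom (2 free
    parameters per context per extra group).
    """
    groups: dict = {}
    for s, g in grouping.assignment.items():
        if s in counts_by_strain:
            groups.setdefault(g, []).append(s)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with data")

    def merged(members):
        out = {}
        for ctx in CONTEXTS:
            xs = [counts_by_strain[s][ctx][0] for s in members
                  if ctx in counts_by_strain[s]]
            ns = [counts_by_strain[s][ctx][1] for s in members
                  if ctx in counts_by_strain[s]]
            if xs:
                out[ctx] = (np.concatenate(xs), np.concatenate(ns))
        return out

    gcounts = {g: merged(members) for g, members in groups.items()}
    lr_total, base_df = 0.0, 0
    per_ctx_p = {}
    n_groups = len(groups)
    for ctx in CONTEXTS:
        have = [g for g in gcounts if ctx in gcounts[g]]
        if not have:
            continue
        base_df += 2
        xc = np.concatenate([gcounts[g][ctx][0] for g in have])
        nc = np.concatenate([gcounts[g][ctx][1] for g in have])
        pc = fit_betabinom_mle(np.column_stack([xc, nc]))
        ll_c = loglik(xc, nc, pc.alpha, pc.beta)
        ll_s = 0.0
        for g in have:
            x, n = gcounts[g][ctx]
            pg = fit_betabinom_mle(np.column_stack([x, n]))
            ll_s += loglik(x, n, pg.alpha, pg.beta)
        lr_ctx = max(0.0, 2.0 * (ll_s - ll_c))
        per_ctx_p[ctx] = float(stats.chi2.sf(lr_ctx, 2 * (n_groups - 1)))
        lr_total += lr_ctx
    if base_df == 0:
        raise ValueError("no context with data in any group")
    df = base_df * (n_groups - 1)
    p = float(stats.chi2.sf(lr_total, df))
    return Dmr(chrom, start, end, grouping, float(lr_total), df, p,
               per_context_p=per_ctx_p)


def resolve_overlaps(dmrs) -> list:
    """Greedy selection by ascending grouping diversity.

    A DMR is kept iff it overlaps no already-kept DMR; ties broken by
    genome order, so the output is deterministic.  The result is
    returned in genome order and is overlap-free.
    """
    ranked = sorted(dmrs, key=lambda d: (d.grouping_diversity, d.chrom, d.start, d.end))
    kept = []
    for d in ranked:
        clash = any(
            d.chrom == k.chrom and d.start <= k.end and d.end >= k.start
            for k in kept
        )
        if not clash:
            kept.append(d)
    kept.sort(key=lambda d: (d.chrom, d.start, d.end))
    return kept


def classify_hdmrs(
    dmrs,
    min_length: int = 50,
    min_fold: float = 3.0,
    min_rate: float = 0.20,
    min_context_sites: int = 5,
) -> list:
    """hDMRs: DMRs longer than ``min_length`` bp with a more than
    ``min_fold``-fold rate difference in >= 1 context having >=
    ``min_context_sites`` cytosines, and a top group rate above
    ``min_rate``.

    A zero rate in the lower group gives an infinite fold change, which
    passes the fold criterion provided the high group clears the
    minimum-rate threshold.
    """
    out = []
    for d in dmrs:
        if d.length <= min_length or not d.group_rates:
            continue
        # overall rate per group (pooled over contexts)
        overall = {}
        for g, per_ctx in d.group_rates.items():
            meth = sum(v[0] for v in per_ctx.values())
            tot = sum(v[1] for v in per_ctx.values())
            overall[g] = meth / tot if tot > 0 else float("nan")
        max_overall = np.nanmax(list(overall.values()))
        if not (max_overall > min_rate):
            continue
        best_ctx, best_fold = None, 0.0
        for ctx in CONTEXTS:
            rates = []
            for g, per_ctx in d.group_rates.items():
                if ctx in per_ctx:
                    meth, tot, nsites = per_ctx[ctx]
                    if tot > 0 and nsites >= min_context_sites:
                        rates.append(meth / tot)
            if len(rates) < 2:
                continue
            hi, lo = max(rates), min(rates)
            fold = np.inf if lo == 0 else hi / lo
            if fold > best_fold:
                best_ctx, best_fold = ctx, fold
        if best_ctx is not None and best_fold > min_fold:
            out.append(HDmr(d, float(best_fold), best_ctx, float(max_overall)))
    return out


# ---------------------------------------------------------------------------
# end-to-end pipeline

def call_dmrs(
    pools,
    mrs_by_strain: dict,
    alpha_fdr: float = 0.01,
    min_sites: int = 10,
    min_cov: int = 3,
    use_prefilter: bool = True,
) -> tuple:
    """Full DMR calling from per-strain MRs and read counts.

    Returns ``(dmrs, pairwise_tests)`` where ``dmrs`` is the final
    non-overlapping set (q < ``alpha_fdr`` at the group level) with
    group rates attached.
    """
    if isinstance(pools, dict):
        pools = list(pools.values())
    strain_data = {p.accession_id: StrainData(p) for p in pools}
    candidates = build_candidates(mrs_by_strain)
    candidates = filter_candidates(candidates, strain_data,
                                   min_sites=min_sites, min_cov=min_cov)

    tests = []
    seg_counts_cache: dict = {}

    def seg_counts(strain, cand):
        key = (strain, cand.chrom, cand.start, cand.end)
        if key not in seg_counts_cache:
            seg_counts_cache[key] = strain_data[strain].counts(
                cand.chrom, cand.start, cand.end
            )
        return seg_counts_cache[key]

    for cand in candidates:
        for s1, s2 in cand.admissible_pairs:
            ca = seg_counts(s1, cand)
            cb = seg_counts(s2, cand)
            if not ca and not cb:
                continue
            t = lrt_pairwise(cand.chrom, cand.start, cand.end, s1, s2, ca, cb)
            tests.append(t)
    if tests:
        q = storey_qvalues([t.p_value for t in tests])
        for t, qv in zip(tests, q):
            t.q_value = float(qv)

    # per-region significant edges -> grouping -> group-level test
    by_region: dict = {}
    for t in tests:
        by_region.setdefault((t.chrom, t.start, t.end), []).append(t)

    group_dmrs = []
    for (chrom, start, end), rtests in sorted(by_region.items()):
        edges = [
            (t.strain_a, t.strain_b)
            for t in rtests
            if t.q_value < alpha_fdr and (t.prefilter_pass or not use_prefilter)
        ]
        if not edges:
            continue
        strains = sorted(
            {t.strain_a for t in rtests} | {t.strain_b for t in rtests}
        )
        counts_by_strain = {
            s: strain_data[s].counts(chrom, start, end) for s in strains
        }
        counts_by_strain = {s: c for s, c in counts_by_strain.items() if c}
        strain_means = {}
        for s in counts_by_strain:
            mus = []
            for ctx in CONTEXTS:
                if ctx in counts_by_strain[s]:
                    x, n = counts_by_strain[s][ctx]
                    mus.append(float(x.sum() / n.sum()))
                else:
                    mus.append(np.nan)
            strain_means[s] = np.array(mus)
        grouping = group_strains(list(counts_by_strain), edges, strain_means)
        if len(set(grouping.assignment.values())) < 2:
            continue
        dmr = group_level_test(chrom, start, end, grouping, counts_by_strain)
        # attach accumulated group rates for hDMR classification
        rates: dict = {}
        for s, g in grouping.assignment.items():
            per_ctx = strain_data[s].context_rates(chrom, start, end)
            acc = rates.setdefault(g, {})
            for ctx, (meth, tot, nsites) in per_ctx.items():
                m0, t0, s0 = acc.get(ctx, (0.0, 0.0, 0))
                acc[ctx] = (m0 + meth, t0 + tot, max(s0, nsites))
        dmr.group_rates = rates
        group_dmrs.append(dmr)

    if group_dmrs:
        q = storey_qvalues([d.p_value for d in group_dmrs])
        for d, qv in zip(group_dmrs, q):
            d.q_value = float(qv)
        group_dmrs = [d for d in group_dmrs if d.q_value < alpha_fdr]
        for d in group_dmrs:
            d.significant_contexts = tuple(
                ctx for ctx, pv in d.per_context_p.items() if pv < alpha_fdr
            )
    final = resolve_overlaps(group_dmrs)
    return final, tests
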