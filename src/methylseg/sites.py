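"""Calling of methylated sites and differentially methylated positions.

A cytosine is called methylated when its replicate-accumulated read
counts are inconsistent with the false-methylation rate estimated from
the unmethylated chloroplast (one-sided binomial test, Storey FDR).
Differentially methylated positions (DMPs) between two accessions are
found with Fisher's exact test on pooled counts, after excluding
positions whose two replicates disagree with each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fdr import storey_qvalues
from .io import SamplePool


@dataclass(frozen=True)
class SiteCall:
    chrom: str
    pos: int
    strand: str
    p_value: float
    q_value: float
    is_methylated: bool


@dataclass(frozen=True)
class DmpCall:
    chrom: str
    pos: int
    strand: str
    strain_a: str
    strain_b: str
    p_value: float
    q_value: float
    rate_a: float
    rate_b: float

    @property
    def strains(self) -> frozenset:
        return frozenset((self.strain_a, self.strain_b))


def call_methylated_sites(pool: SamplePool, fmr: float, alpha_fdr: float = 0.05):
    """One-sided binomial test of each position against the false-methylation rate.

    ``fmr`` is the apparent methylation rate of the unconverted control;
    positions with excess methylated reads (q < ``alpha_fdr``) are called
    methylated.
    """
    if not (0.0 < fmr < 1.0):
        raise ValueError("fmr must be in (0, 1); 0 gives a degenerate null")
    acc = pool.accumulated()
    acc = acc[acc["total_reads"] > 0]
    x = acc["meth_reads"].to_numpy(int)
    n = acc["total_reads"].to_numpy(int)
    # P(X >= x) under Binomial(n, fmr)
    p = stats.binom.sf(x - 1, n, fmr)
    q = storey_qvalues(p)
    return [
        SiteCall(c, int(pos), s, float(pv), float(qv), bool(qv < alpha_fdr))
        for c, pos, s, pv, qv in zip(acc["chrom"], acc["pos"], acc["strand"], p, q)
    ]


def replicate_concordance_filter(pool: SamplePool, alpha_fdr: float = 0.05):
    """Positions whose two replicates disagree (Fisher exact + FDR).

    Returns the set of (chrom, pos, strand) keys to exclude from DMP
    calling.  Requires exactly two replicates.
    """
    if len(pool.replicates) != 2:
        raise ValueError("replicate concordance filter needs exactly 2 replicates")
    a, b = (r.df for r in pool.replicates)
    keys = ["chrom", "pos", "strand"]
    merged = a.merge(b, on=keys + ["context"], suffixes=("_1", "_2"))
    if merged.empty:
        return set()
    p = np.array(
        [
            fisher_exact_2x2(
                int(r.meth_reads_1), int(r.total_reads_1 - r.meth_reads_1),
                int(r.meth_reads_2), int(r.total_reads_2 - r.meth_reads_2),
            )
            for r in merged.itertuples(index=False)
        ]
    )
    q = storey_qvalues(p)
    bad = merged.loc[q < alpha_fdr, keys]
    return set(zip(bad["chrom"], bad["pos"], bad["strand"]))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for the table [[a, b], [c, d]]."""
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def call_dmps(pools, methylated_union, alpha_fdr: float = 0.05,
              excluded=frozenset()):
    """Pairwise Fisher exact tests at methylated positions.

    For every pair of accessions and every position in
    ``methylated_union`` (minus replicate-discordant positions in
    ``excluded``), test the pooled 2x2 count table; q-values are
    computed per strain-pair contrast.  Returns a list of
    :class:`DmpCall` (all tested positions, with the DMP flag implied by
    q < ``alpha_fdr`` left to the caller via the q-value).
    """
    universe = set(methylated_union) - set(excluded)
    acc = {}
    for pool in pools:
        df = pool.accumulated()
        key = list(zip(df["chrom"], df["pos"], df["strand"]))
        df = df.assign(_key=key).set_index("_key")
        acc[pool.accession_id] = df

    calls = []
    ids = sorted(acc)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            da, db = acc[ids[i]], acc[ids[j]]
            shared = [k for k in universe if k in da.index and k in db.index]
            if not shared:
                continue
            shared.sort()
            sa = da.loc[shared]
            sb = db.loc[shared]
            p = np.array(
                [
                    fisher_exact_2x2(
                        int(xa), int(na - xa), int(xb), int(nb - xb)
                    )
                    for xa, na, xb, nb in zip(
                        sa["meth_reads"], sa["total_reads"],
                        sb["meth_reads"], sb["total_reads"],
                    )
                ]
            )
            q = storey_qvalues(p)
            for k, pv, qv, xa, na, xb, nb in zip(
                shared, p, q, sa["meth_reads"], sa["total_reads"],
                sb["meth_reads"], sb["total_reads"],
            ):
                calls.append(
                    DmpCall(
                        k[0], int(k[1]), k[2], ids[i], ids[j],
                        float(pv), float(qv),
                        float(xa) / float(na) if na else float("nan"),
                        float(xb) / float(nb) if nb else float("nan"),
                    )
                )
    return calls


def count_dmps(calls, alpha_fdr: float = 0.05) -> int:
    """Number of unique positions significant in at least one pair."""
    sig = {(c.chrom, c.pos, c.strand) for c in calls if c.q_value < alpha_fdr}
    return len(sig)


def epiallele_frequency(assignments: dict, reference_strain: str | None = None):
    """Minor (or non-reference) epiallele count per variable locus.

    Parameters
    ----------
    assignments
        Mapping locus -> mapping strain -> group label (epiallele state).
    reference_strain
        If given, the frequency is the number of strains whose state
        differs from the reference strain's; otherwise the size of the
        minority group.

    Returns a pandas Series indexed by locus.
    """
    freqs = {}
    for locus, groups in assignments.items():
        if reference_strain is not None:
            ref = groups[reference_strain]
            freqs[locus] = sum(1 for s, g in groups.items() if g != ref)
        else:
            sizes = pd.Series(list(groups.values())).value_counts()
            freqs[locus] = int(sizes.min()) if len(sizes) > 1 else 0
    return pd.Series(freqs, dtype=int)
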