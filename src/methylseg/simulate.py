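"""Synthetic methylome generators.

The generators mirror the statistical assumptions of the analysis
stages: hidden two-state (LOW/HIGH) methylation along the genome with
context-specific beta-binomial read counts at Poisson depth, strains
diverging from a common ancestor by per-site epimutation with frequent
reversion, pools of siblings whose counts sum, and genetic variants
accumulating as a neutral clock.  All generators are deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CONTEXTS, MethylomeTable, SamplePool


def _default_high_mu():
    return {"CG": 0.80, "CHG": 0.65, "CHH": 0.35}


def _default_low_mu():
    return {"CG": 0.03, "CHG": 0.03, "CHH": 0.03}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic population.

    Defaults follow the experimental design being emulated: 13
    accessions sequenced as two pools of 8-10 siblings at ~18x depth,
    two-state methylation with strong persistence along the genome and
    context-specific rate distributions.
    """

    n_strains: int = 13
    n_replicates: int = 2
    n_chromosomes: int = 1
    n_positions: int = 3000  # cytosines per chromosome
    context_proportions: tuple = (0.15, 0.15, 0.70)  # CG, CHG, CHH
    high_mu: dict = field(default_factory=_default_high_mu)
    low_mu: dict = field(default_factory=_default_low_mu)
    dispersion: float = 12.0  # alpha + beta of the rate Beta
    persistence: float = 0.95  # P(state_t+1 = state_t)
    start_high: float = 0.25
    mean_depth: float = 18.0  # Poisson mean per replicate
    mean_spacing: float = 8.0  # bp between consecutive cytosines
    epimutation_rate: float = 0.0  # per site per generation state flips
    reversion_rate: float = 0.5  # chance a flip reverts next generation
    generations: int = 100  # since the common ancestor, per strain
    snp_rate: float = 0.7  # SNPs per generation (neutral clock)
    pool_size: int = 8
    dmr_high_mu: float = 0.8  # planted-DMR effect rate, methylated epiallele
    dmr_low_mu: float = 0.1  # planted-DMR effect rate, unmethylated epiallele
    seed: int = 0


def _beta_params(mu: float, nu: float) -> tuple:
    mu = min(max(mu, 1e-4), 1.0 - 1e-4)
    return mu * nu, (1.0 - mu) * nu


def _positions(cfg: SimulationConfig, rng) -> np.ndarray:
    gaps = rng.geometric(1.0 / cfg.mean_spacing, size=cfg.n_positions)
    return np.cumsum(gaps)


def _contexts(cfg: SimulationConfig, rng) -> np.ndarray:
    return rng.choice(len(CONTEXTS), size=cfg.n_positions,
                      p=np.asarray(cfg.context_proportions))


def _hidden_path(cfg: SimulationConfig, rng) -> np.ndarray:
    path = np.empty(cfg.n_positions, dtype=int)
    path[0] = int(rng.random() < cfg.start_high)
    stay = cfg.persistence
    flips = rng.random(cfg.n_positions - 1) >= stay
    for t in range(1, cfg.n_positions):
        path[t] = path[t - 1] ^ int(flips[t - 1])
    return path


def _draw_counts(states, ctx_idx, cfg: SimulationConfig, rng,
                 rates: np.ndarray | None = None):
    """Counts at Poisson depth given hidden states; returns (x, n, rates)."""
    T = states.size
    if rates is None:
        rates = np.empty(T)
        for s, mus in ((0, cfg.low_mu), (1, cfg.high_mu)):
            for ci, ctx in enumerate(CONTEXTS):
                mask = (states == s) & (ctx_idx == ci)
                if np.any(mask):
                    a, b = _beta_params(mus[ctx], cfg.dispersion)
                    rates[mask] = rng.beta(a, b, size=mask.sum())
    n = rng.poisson(cfg.mean_depth, size=T)
    x = rng.binomial(n, rates)
    return x, n, rates


def _table_from_arrays(chrom, pos, ctx_idx, x, n, sample_id, replicate_id):
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "strand": "+",
            "context": [CONTEXTS[i] for i in ctx_idx],
            "meth_reads": x,
            "total_reads": n,
            "qual_ok": True,
        }
    )
    return MethylomeTable(df, sample_id=sample_id, replicate_id=replicate_id)


def simulate_methylome(cfg: SimulationConfig,
                       rng: np.random.Generator | None = None):
    """One strain's methylome plus the true hidden state path.

    Returns ``(table, truth)`` where truth is a DataFrame with columns
    chrom, pos, state (0 = LOW, 1 = HIGH).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    tables, truths = [], []
    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1}"
        pos = _positions(cfg, rng)
        ctx = _contexts(cfg, rng)
        path = _hidden_path(cfg, rng)
        x, n, _ = _draw_counts(path, ctx, cfg, rng)
        tables.append(
            _table_from_arrays(chrom, pos, ctx, x, n, "sim", "r1").df
        )
        truths.append(pd.DataFrame({"chrom": chrom, "pos": pos, "state": path}))
    table = MethylomeTable(pd.concat(tables, ignore_index=True), "sim", "r1")
    return table, pd.concat(truths, ignore_index=True)


def epimutation_flip_probability(rate: float, generations: float,
                                 reversion_rate: float) -> float:
    """Probability a site's state differs from the ancestor's.

    Gains and losses with frequent reversion behave like a two-state
    switching process, so divergence saturates rather than growing
    linearly: p(g) = (1 - exp(-2 * r_eff * g)) / 2 with the effective
    rate r_eff = rate * (1 - reversion_rate).  Concave in g, capped at
    1/2 (the stationary disagreement probability).
    """
    r_eff = rate * (1.0 - reversion_rate)
    return 0.5 * (1.0 - np.exp(-2.0 * r_eff * generations))


@dataclass
class PlantedDmr:
    chrom: str
    start: int
    end: int
    low_strains: frozenset  # strains switched to LOW in this window
    positions: tuple


def simulate_population(cfg: SimulationConfig,
                        rng: np.random.Generator | None = None,
                        planted_fraction: float = 0.5,
                        min_planted_run: int = 12):
    """A multi-strain population with planted differential methylation.

    All strains share an ancestral two-state path.  A fraction of the
    HIGH runs is planted as a true DMR: a random non-empty proper
    subset of strains carries the unmethylated epiallele
    (rate ~ ``cfg.dmr_low_mu``) while the rest stay methylated at
    ``cfg.dmr_high_mu``, uniformly across contexts; the partition is
    recorded.  Remaining HIGH runs are planted negatives.  Per-site
    epimutation noise flips additional single positions per strain at
    ``cfg.epimutation_rate`` per generation, with reversions making the
    accumulation sub-linear.  Genetic variants accumulate as a Poisson
    clock, giving a strain x variant genotype matrix.

    Returns ``(pools, planted, negatives, genotypes)``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    strains = [f"S{i:02d}" for i in range(cfg.n_strains)]
    pools, planted, negatives = {}, [], []
    per_strain_states = {s: [] for s in strains}
    per_strain_mu_override = {s: [] for s in strains}  # nan = state default
    geometry = []

    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1}"
        pos = _positions(cfg, rng)
        ctx = _contexts(cfg, rng)
        anc = _hidden_path(cfg, rng)
        geometry.append((chrom, pos, ctx))

        # HIGH runs of the ancestral path
        runs = []
        t = 0
        while t < anc.size:
            if anc[t] == 1:
                u = t
                while u + 1 < anc.size and anc[u + 1] == 1:
                    u += 1
                runs.append((t, u))
                t = u + 1
            else:
                t += 1

        states = {s: anc.copy() for s in strains}
        override = {s: np.full(anc.size, np.nan) for s in strains}
        for (t0, t1) in runs:
            window = (chrom, int(pos[t0]), int(pos[t1]))
            if (t1 - t0 + 1) >= min_planted_run and rng.random() < planted_fraction:
                k = int(rng.integers(1, cfg.n_strains))
                low = frozenset(
                    str(x) for x in rng.choice(strains, size=k, replace=False)
                )
                for s in strains:
                    if s in low:
                        states[s][t0 : t1 + 1] = 0
                        override[s][t0 : t1 + 1] = cfg.dmr_low_mu
                    else:
                        override[s][t0 : t1 + 1] = cfg.dmr_high_mu
                planted.append(
                    PlantedDmr(window[0], window[1], window[2], low,
                               tuple(range(t0, t1 + 1)))
                )
            else:
                negatives.append(window)

        # epimutation noise: isolated state flips, sub-linear via reversion
        if cfg.epimutation_rate > 0:
            flip_p = epimutation_flip_probability(
                cfg.epimutation_rate, cfg.generations, cfg.reversion_rate
            )
            for s in strains:
                flips = rng.random(anc.size) < flip_p
                states[s][flips] ^= 1
                override[s][flips] = np.nan

        for s in strains:
            per_strain_states[s].append(states[s])
            per_strain_mu_override[s].append(override[s])

    for s in strains:
        # biological per-site rates shared across replicate pools
        rates_per_chrom = []
        for (chrom, pos, ctx), st, ov in zip(
            geometry, per_strain_states[s], per_strain_mu_override[s]
        ):
            rates = np.empty(st.size)
            for state, mus in ((0, cfg.low_mu), (1, cfg.high_mu)):
                for ci, cname in enumerate(CONTEXTS):
                    mask = (st == state) & (ctx == ci)
                    if np.any(mask):
                        a, b = _beta_params(mus[cname], cfg.dispersion)
                        rates[mask] = rng.beta(a, b, size=mask.sum())
            planted_mask = ~np.isnan(ov)
            if np.any(planted_mask):
                for mu in np.unique(ov[planted_mask]):
                    mask = planted_mask & (ov == mu)
                    a, b = _beta_params(float(mu), cfg.dispersion)
                    rates[mask] = rng.beta(a, b, size=mask.sum())
            rates_per_chrom.append(rates)
        reps = []
        for r in range(cfg.n_replicates):
            dfs = []
            for (chrom, pos, ctx), st, rates in zip(
                geometry, per_strain_states[s], rates_per_chrom
            ):
                x, n, _ = _draw_counts(st, ctx, cfg, rng, rates=rates)
                dfs.append(
                    _table_from_arrays(chrom, pos, ctx, x, n, s, f"r{r+1}").df
                )
            reps.append(
                MethylomeTable(pd.concat(dfs, ignore_index=True), s, f"r{r+1}")
            )
        pools[s] = SamplePool(accession_id=s, replicates=reps)

    genotypes = simulate_genotypes_clock(cfg, rng)
    return pools, planted, negatives, genotypes


def simulate_genotypes_clock(cfg: SimulationConfig, rng) -> pd.DataFrame:
    """Neutral SNP clock: each strain carries private Poisson mutations."""
    strains = [f"S{i:02d}" for i in range(cfg.n_strains)]
    counts = rng.poisson(cfg.snp_rate * cfg.generations, size=cfg.n_strains)
    total = int(counts.sum())
    G = np.zeros((cfg.n_strains, max(total, 1)), dtype=int)
    col = 0
    for i, k in enumerate(counts):
        G[i, col : col + k] = 1
        col += k
    return pd.DataFrame(G, index=strains)


def simulate_individuals(cfg: SimulationConfig, n_individuals: int,
                         flip_prob: float = 0.02,
                         rng: np.random.Generator | None = None):
    """Sibling individuals sharing a parental methylome.

    Each individual inherits the parent's hidden states with
    independent per-site flips at ``flip_prob``, modelling
    inter-individual epigenetic heterogeneity within a family.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pos = _positions(cfg, rng)
    ctx = _contexts(cfg, rng)
    anc = _hidden_path(cfg, rng)
    tables = []
    for i in range(n_individuals):
        st = anc.copy()
        flips = rng.random(anc.size) < flip_prob
        st[flips] ^= 1
        x, n, _ = _draw_counts(st, ctx, cfg, rng)
        tables.append(
            _table_from_arrays("chr1", pos, ctx, x, n, f"ind{i}", "r1")
        )
    return tables


def simulate_sibling_families(cfg: SimulationConfig,
                              n_families: int = 2,
                              n_per_family: int = 4,
                              family_divergence: float = 0.02,
                              flip_prob: float = 0.03,
                              rng: np.random.Generator | None = None):
    """Families of sibling individuals on a shared genome.

    Family founders diverge from a common ancestral methylome by
    per-site state flips at ``family_divergence``; each sibling then
    carries additional private flips at ``flip_prob``.  Returns a list
    of families, each a list of MethylomeTable, sharing one position
    universe (so they can be pooled and compared).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pos = _positions(cfg, rng)
    ctx = _contexts(cfg, rng)
    anc = _hidden_path(cfg, rng)
    families = []
    for fam in range(n_families):
        founder = anc.copy()
        flips = rng.random(anc.size) < family_divergence
        founder[flips] ^= 1
        members = []
        for i in range(n_per_family):
            st = founder.copy()
            flips = rng.random(anc.size) < flip_prob
            st[flips] ^= 1
            x, n, _ = _draw_counts(st, ctx, cfg, rng)
            members.append(
                _table_from_arrays("chr1", pos, ctx, x, n,
                                   f"f{fam}i{i}", "r1")
            )
        families.append(members)
    return families


def simulate_pools(individual_tables, rng=None,
                   resample_depth: bool = False) -> MethylomeTable:
    """Pool individuals in silico: read counts sum per position.

    With ``resample_depth=True`` the summed counts are hypergeometrically
    subsampled back to the average per-individual coverage, modelling a
    library sequenced from pooled DNA at standard depth rather than a
    concatenation of every member's reads.  Requires ``rng``.
    """
    if len(individual_tables) < 2:
        raise ValueError("need at least 2 individuals to pool")
    base = individual_tables[0].df
    key_cols = ["chrom", "pos", "strand", "context"]
    meth = base["meth_reads"].to_numpy().copy()
    tot = base["total_reads"].to_numpy().copy()
    for t in individual_tables[1:]:
        df = t.df
        if len(df) != len(base) or not (
            df[key_cols].reset_index(drop=True)
            .equals(base[key_cols].reset_index(drop=True))
        ):
            raise ValueError("individuals have mismatched position universes")
        meth += df["meth_reads"].to_numpy()
        tot += df["total_reads"].to_numpy()
    out = base.copy()
    if resample_depth:
        if rng is None:
            raise ValueError("resample_depth requires an rng")
        target = np.maximum(
            np.rint(tot / len(individual_tables)).astype(int), 0
        )
        draw = np.minimum(target, tot)
        meth = np.array([
            rng.hypergeometric(m, t - m, d) if d > 0 else 0
            for m, t, d in zip(meth, tot, draw)
        ])
        tot = draw
    out["meth_reads"] = meth
    out["total_reads"] = tot
    return MethylomeTable(out, sample_id="pool", replicate_id="r1")


def simulate_genotypes(n_strains: int, n_variants: int,
                       rng: np.random.Generator,
                       maf_min: float = 0.1) -> np.ndarray:
    """Random biallelic haploid genotypes with bounded allele frequency."""
    f = rng.uniform(maf_min, 1.0 - maf_min, size=n_variants)
    return (rng.random((n_strains, n_variants)) < f).astype(int)


def simulate_phenotype(K: np.ndarray, h2: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Phenotype with genetic variance fraction h2 given kinship K."""
    n = K.shape[0]
    S, U = np.linalg.eigh(K)
    S = np.maximum(S, 0.0)
    g = U @ (np.sqrt(S) * rng.standard_normal(n))
    g = g / g.std() if g.std() > 0 else g
    e = rng.standard_normal(n)
    e = e / e.std()
    return np.sqrt(h2) * g + np.sqrt(1.0 - h2) * e
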