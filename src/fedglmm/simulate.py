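"""Pedigree-based federated cohort simulator.

Generates study fixtures with the statistical structure the association
test is built for: founder genotypes from an i.i.d. allele-frequency model,
descendant genotypes by Mendelian gene dropping (one uniformly chosen
haplotype allele per parent per locus, no linkage), a pedigree-expected
numerator relationship matrix, binary phenotypes from a logit-link model
with sparse causal variants, a gender covariate, an explicit polygenic term
b ~ N(0, tau A), and random splits into federated sites.

Each family follows a 4-level, 16-member pedigree: 8 founders and 8
descendants (4 children, 2 grandchildren, 2 great-grandchildren as full
siblings).  Families are simulated independently, so the cohort-wide
relationship matrix is block diagonal before site splitting; random site
assignment scatters relatives across sites, inducing cross-site kinship.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from fedglmm.federation import SiteData
from fedglmm.glmm import CohortData


@dataclass
class Member:
    id: str
    father: str | None
    mother: str | None
    sex: int  # 0/1; founders alternate, descendants assigned


@dataclass
class Pedigree:
    """A single family pedigree; parents precede children."""

    members: list[Member]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for m in self.members:
            for par in (m.father, m.mother):
                if par is not None and par not in seen:
                    raise ValueError(f"parent {par} of {m.id} not defined earlier")
            if m.id in seen:
                raise ValueError(f"duplicate member id {m.id}")
            seen.add(m.id)

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def founder_ids(self) -> list[str]:
        return [m.id for m in self.members if m.father is None]

    def index(self) -> dict[str, int]:
        return {m.id: i for i, m in enumerate(self.members)}


def default_family(prefix: str = "F") -> Pedigree:
    """The default 16-member family: 8 founders, 8 descendants, 4 levels."""
    mk = lambda i: f"{prefix}_{i}"
    members = [Member(mk(i), None, None, sex=i % 2) for i in range(8)]
    # generation 2: four children of the founder couples
    for c, (fa, mo) in enumerate([(0, 1), (2, 3), (4, 5), (6, 7)]):
        members.append(Member(mk(8 + c), mk(fa), mk(mo), sex=c % 2))
    # generation 3: two grandchildren
    members.append(Member(mk(12), mk(8), mk(9), sex=0))
    members.append(Member(mk(13), mk(10), mk(11), sex=1))
    # generation 4: two great-grandchildren (full siblings)
    members.append(Member(mk(14), mk(12), mk(13), sex=0))
    members.append(Member(mk(15), mk(12), mk(13), sex=1))
    return Pedigree(members=members)


@dataclass
class SimConfig:
    """Study-generation parameters.

    Defaults reproduce the main simulated study design: 400 families of 16
    (6,400 subjects) subsampled to 6,000, 3 sites, 20 causal variants with
    N(0, 0.5 sd) effects, gender effect 0.1, environmental noise sd 0.5,
    polygenic variance tau = 0.5 on the link scale, founder allele
    frequencies Uniform(0.05, 0.5).
    """

    n_families: int = 400
    n_snps: int = 5000
    n_causal: int = 20
    beta_sd: float = 0.5
    env_sd: float = 0.5
    gender_effect: float = 0.1
    tau: float = 0.5
    allele_freq_range: tuple[float, float] = (0.05, 0.5)
    maf_threshold: float = 0.01
    n_sites: int = 3
    seed: int = 0
    subsample_to: int | None = 6000

    def __post_init__(self) -> None:
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("allele frequencies must lie in (0, 1)")
        if self.subsample_to is not None and self.subsample_to > 16 * self.n_families:
            raise ValueError("subsample_to exceeds simulated cohort size")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def simulate_founders(
    freqs: np.ndarray, n_founders: int, rng: np.random.Generator
) -> np.ndarray:
    """Founder haplotypes: allele 1 drawn i.i.d. per haplotype with prob f.

    Returns an (n_founders, n_snps, 2) array of 0/1 alleles.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs < 0) | (freqs > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    u = rng.random((n_founders, freqs.shape[0], 2))
    return (u < freqs[None, :, None]).astype(np.int8)


def gene_drop(
    pedigree: Pedigree, founder_haplotypes: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Drop alleles through the pedigree, one allele per parent per locus.

    Each descendant inherits, independently per variant, a uniformly chosen
    haplotype allele from each parent.  Returns (n_members, n_snps, 2).
    """
    idx = pedigree.index()
    founders = pedigree.founder_ids
    m = founder_haplotypes.shape[1]
    haps = np.zeros((pedigree.n, m, 2), dtype=np.int8)
    fpos = {fid: k for k, fid in enumerate(founders)}
    for member in pedigree.members:
        i = idx[member.id]
        if member.father is None:
            haps[i] = founder_haplotypes[fpos[member.id]]
        else:
            if member.mother is None:
                raise ValueError(f"member {member.id} has only one parent")
            for h, parent in enumerate((member.father, member.mother)):
                pick = rng.integers(0, 2, size=m)
                haps[i, :, h] = haps[idx[parent], np.arange(m), pick]
    return haps


def pedigree_relationship(pedigree: Pedigree) -> np.ndarray:
    """Expected numerator relationship matrix A by the tabular recursion.

    Founders: A_ii = 1, unrelated founders 0.  For a child c of (f, m):
    A_cx = (A_fx + A_mx)/2 for earlier x, and A_cc = 1 + A_fm/2.
    """
    idx = pedigree.index()
    n = pedigree.n
    A = np.zeros((n, n))
    for member in pedigree.members:
        i = idx[member.id]
        if member.father is None:
            A[i, i] = 1.0
        else:
            f, m = idx[member.father], idx[member.mother]
            for x in range(i):
                A[i, x] = A[x, i] = 0.5 * (A[f, x] + A[m, x])
            A[i, i] = 1.0 + 0.5 * A[f, m]
    return A


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def simulate_phenotype(
    G: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    V: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Binary phenotype from the logit-link model.

    eta_i = sum_c g_ic beta_c + gender_i * gender_effect + b_i + eps_i with
    beta_c ~ N(0, beta_sd), eps_i ~ N(0, env_sd), b ~ N(0, tau V) (polygenic
    term, drawn when tau > 0 and V is given); y_i ~ Bernoulli(expit(eta_i)).
    ``G`` is n x m dosages.  Returns (y, covariates, truth metadata).
    """
    n, m = G.shape
    gender = rng.integers(0, 2, size=n).astype(float)
    causal = rng.choice(m, size=config.n_causal, replace=False) if config.n_causal else np.array([], dtype=int)
    beta = rng.normal(0.0, config.beta_sd, size=config.n_causal)
    eta = gender * config.gender_effect
    if config.n_causal:
        eta = eta + G[:, causal] @ beta
    b = np.zeros(n)
    if config.tau > 0 and V is not None:
        # draw b ~ N(0, tau V) through a jittered Cholesky factor
        jitter = 1e-8 * max(1.0, float(np.diag(V).max()))
        L = np.linalg.cholesky(V + jitter * np.eye(n))
        b = np.sqrt(config.tau) * (L @ rng.standard_normal(n))
        eta = eta + b
    if config.env_sd > 0:
        eta = eta + rng.normal(0.0, config.env_sd, size=n)
    y = (rng.random(n) < expit(eta)).astype(float)
    truth = {
        "causal_indices": causal.tolist(),
        "beta": beta.tolist(),
        "tau": config.tau,
        "gender_effect": config.gender_effect,
        "env_sd": config.env_sd,
    }
    return y, gender[:, None], truth


# ---------------------------------------------------------------------------
# study assembly
# ---------------------------------------------------------------------------


@dataclass
class Study:
    """A simulated federated study in concatenated site order."""

    pooled: CohortData
    sites: list[SiteData]
    G: np.ndarray  # m x n dosages, pooled order
    snp_ids: list[str]
    freqs: np.ndarray
    truth: dict
    config: SimConfig = field(repr=False, default=None)

    def save(self, outdir) -> None:
        """Write site bundles, kinship, pooled genotypes and truth metadata."""
        from pathlib import Path

        import pandas as pd

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        ids = [str(s) for s in self.pooled.sample_ids]
        kin = pd.DataFrame(self.pooled.V, index=ids, columns=ids)
        kin.to_csv(out / "kinship.tsv", sep="\t")
        lo = 0
        for site in self.sites:
            sid = [str(x) for x in site.sample_ids]
            pd.DataFrame(
                {"sample_id": sid, "outcome": site.y.astype(int), "gender": site.X[:, 1]}
            ).to_csv(out / f"{site.site_id}.pheno.tsv", sep="\t", index=False)
            pd.DataFrame(site.G, index=self.snp_ids, columns=sid).to_csv(
                out / f"{site.site_id}.dosage.tsv", sep="\t", index_label="snp_id"
            )
            lo += site.n
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1)


def assemble_study(config: SimConfig) -> Study:
    """Simulate a full federated study from a configuration.

    Families are gene-dropped independently, concatenated, randomly
    subsampled to ``subsample_to`` subjects, phenotyped, and randomly
    partitioned into ``n_sites`` (family members may land on different
    sites, creating cross-site kinship).  The returned pooled cohort, site
    bundles and kinship matrix all share the concatenated site order.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.allele_freq_range
    freqs = rng.uniform(lo, hi, size=config.n_snps)
    fam = default_family()
    A_fam = pedigree_relationship(fam)
    doses, ids = [], []
    for f in range(config.n_families):
        ped = default_family(prefix=f"fam{f}")
        founders = simulate_founders(freqs, len(ped.founder_ids), rng)
        haps = gene_drop(ped, founders, rng)
        doses.append(haps.sum(axis=2).astype(float))
        ids.extend(m.id for m in ped.members)
    G = np.vstack(doses)  # n_total x m
    n_total = G.shape[0]
    V = np.zeros((n_total, n_total))
    for f in range(config.n_families):
        sl = slice(16 * f, 16 * (f + 1))
        V[sl, sl] = A_fam
    ids = np.asarray(ids)

    if config.subsample_to is not None and config.subsample_to < n_total:
        keep = np.sort(rng.choice(n_total, size=config.subsample_to, replace=False))
        G, V, ids = G[keep], V[np.ix_(keep, keep)], ids[keep]
    n = G.shape[0]

    # MAF filter on the pooled dosages (simulator-side preprocessing)
    af = G.mean(axis=0) / 2.0
    keep_snp = np.minimum(af, 1.0 - af) >= config.maf_threshold
    G = G[:, keep_snp]
    snp_ids = [f"snp{i}" for i in np.flatnonzero(keep_snp)]
    freqs_kept = freqs[keep_snp]

    y, gender, truth = simulate_phenotype(G, config, rng, V=V)
    X = np.column_stack([np.ones(n), gender])

    # random site assignment, then reorder everything to site-block order
    assign = rng.integers(0, config.n_sites, size=n)
    order = np.argsort(assign, kind="stable")
    G, V, ids, y, X = G[order], V[np.ix_(order, order)], ids[order], y[order], X[order]
    assign = assign[order]
    pooled = CohortData(sample_ids=ids, y=y, X=X, V=V)
    sites = []
    lo_i = 0
    for j in range(config.n_sites):
        nj = int(np.sum(assign == j))
        hi_i = lo_i + nj
        sites.append(
            SiteData(
                site_id=f"site{j}",
                sample_ids=ids[lo_i:hi_i],
                X=X[lo_i:hi_i],
                y=y[lo_i:hi_i],
                V_block=V[:, lo_i:hi_i],
                G=G[lo_i:hi_i].T.copy(),  # m x n_j
            )
        )
        lo_i = hi_i
    truth.update(
        {
            "seed": config.seed,
            "n_subjects": n,
            "n_snps_kept": int(keep_snp.sum()),
            "site_sizes": [s.n for s in sites],
            "causal_snp_ids": [snp_ids[i] for i in truth["causal_indices"]],
        }
    )
    return Study(
        pooled=pooled,
        sites=sites,
        G=G.T.copy(),  # m x n
        snp_ids=snp_ids,
        freqs=freqs_kept,
        truth=truth,
        config=config,
    )
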