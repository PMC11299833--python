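"""Protocol tests: federated computation must reproduce the pooled engine."""

import numpy as np
import pytest

from fedglmm import federation, glmm
from fedglmm.federation import (
    algorithm1_fed_newton,
    algorithm2_fed_pql,
    algorithm3_fed_score,
    audit_transcript,
    fed_allele_stats,
    fit_null_federated,
    make_server,
    split_cohort,
)
from fedglmm.simulate import SimConfig, assemble_study


def pvals(rows):
    return np.array([r.pval if r.pval is not None else np.nan for r in rows])


@pytest.fixture(scope="module")
def fitted_pair(small_study):
    """Pooled and 3-site federated (mask backend) fits of the same cohort."""
    pooled = glmm.fit_null_pooled(small_study.pooled)
    server = make_server(small_study.pooled.V, backend="mask", seed=99)
    fed = fit_null_federated(small_study.sites, server)
    return small_study, pooled, fed, server


class TestAlgorithm1:
    def test_single_site_equals_pooled_newton(self, small_cohort, rng):
        sites, pooled, _ = split_cohort(small_cohort, 1)
        server = make_server(pooled.V, backend="mask", seed=1)
        fed = algorithm1_fed_newton(sites, server)
        ref = glmm.newton_init_alpha(pooled)
        assert fed.converged and ref.converged
        assert np.max(np.abs(fed.alpha - ref.alpha)) < 1e-9

    def test_three_site_split_matches_pooled(self, small_cohort, rng):
        sites, pooled, _ = split_cohort(small_cohort, 3, rng=rng)
        server = make_server(pooled.V, backend="mask", seed=2)
        fed = algorithm1_fed_newton(sites, server)
        ref = glmm.newton_init_alpha(pooled)
        assert np.max(np.abs(fed.alpha - ref.alpha)) < 1e-6

    def test_gradient_stationary_at_convergence(self, small_cohort, rng):
        from scipy.special import expit

        sites, pooled, _ = split_cohort(small_cohort, 3, rng=rng)
        server = make_server(pooled.V, backend="mock-he", seed=3)
        fed = algorithm1_fed_newton(sites, server)
        pi = expit(pooled.X @ fed.alpha)
        assert np.max(np.abs(pooled.X.T @ (pooled.y - pi))) < 1e-4

    def test_covariate_schema_mismatch_rejected(self, small_cohort):
        sites, pooled, _ = split_cohort(small_cohort, 2)
        sites[1].X = sites[1].X[:, :1]
        server = make_server(pooled.V, seed=4)
        with pytest.raises(ValueError, match="schema"):
            algorithm1_fed_newton(sites, server)


class TestNullModelEquivalence:
    def test_federated_matches_pooled(self, fitted_pair):
        """alpha, tau and b agree between the protocol and the pooled engine."""
        _, pooled, fed, _ = fitted_pair
        assert fed.converged and pooled.converged
        assert np.allclose(fed.alpha, pooled.alpha, rtol=1e-6, atol=1e-8)
        assert fed.tau == pytest.approx(pooled.tau, rel=1e-6, abs=1e-8)
        assert np.allclose(fed.b, pooled.b, rtol=1e-6, atol=1e-8)

    def test_projection_matrices_agree(self, fitted_pair):
        _, pooled, fed, _ = fitted_pair
        scale = np.abs(pooled.P).max()
        assert np.abs(fed.P - pooled.P).max() < 1e-8 * max(1.0, scale)

    def test_block_diagonal_shortcut(self, small_cohort):
        """With zero cross-site kinship the blockwise Sigma inverse is exact."""
        # contiguous whole-family splits: V is block diagonal across sites
        sizes = [16, 32, 16]
        sites, pooled, _ = split_cohort(small_cohort, 3, sizes=sizes)
        s1 = make_server(pooled.V, backend="mock-he", seed=5)
        full = fit_null_federated(sites, s1)
        s2 = make_server(pooled.V, backend="mock-he", seed=5)
        short = fit_null_federated(sites, s2, assume_block_diagonal=True)
        assert np.allclose(full.alpha, short.alpha, atol=1e-8)
        assert full.tau == pytest.approx(short.tau, abs=1e-8)
        assert np.allclose(full.b, short.b, atol=1e-8)

    def test_quantized_transfers_close_to_full_precision(self, small_study):
        server64 = make_server(small_study.pooled.V, backend="mask", seed=6)
        m64 = fit_null_federated(small_study.sites, server64)
        server32 = make_server(small_study.pooled.V, backend="mask", seed=6)
        m32 = fit_null_federated(small_study.sites, server32, quantize=True)
        assert np.allclose(m32.alpha, m64.alpha, rtol=1e-4, atol=1e-6)
        assert m32.tau == pytest.approx(m64.tau, rel=1e-4, abs=1e-6)


class TestScoreEquivalence:
    def test_per_snp_statistics_match_pooled(self, fitted_pair):
        study, pooled, fed, server = fitted_pair
        rows_p = glmm.score_test_chunk(study.G, pooled.P, pooled.ytilde,
                                       snp_ids=study.snp_ids)
        rows_f = algorithm3_fed_score(study.sites, server, fed,
                                      chunk_k=25, snp_ids=study.snp_ids)
        assert len(rows_p) == len(rows_f)
        Tp = np.array([r.score_T for r in rows_p])
        Tf = np.array([r.score_T for r in rows_f])
        vp = np.array([r.var_T for r in rows_p])
        vf = np.array([r.var_T for r in rows_f])
        assert np.allclose(Tf, Tp, rtol=1e-6, atol=1e-6)
        assert np.allclose(vf, vp, rtol=1e-6, atol=1e-6)
        assert np.allclose(pvals(rows_f), pvals(rows_p), rtol=1e-5, atol=1e-8,
                           equal_nan=True)

    def test_chunk_size_invariance(self, small_study):
        """Identical results for any chunking of the variant stream."""
        server = make_server(small_study.pooled.V, backend="mock-he", seed=7)
        fed = fit_null_federated(small_study.sites, server)
        base = None
        for k in (1, 7, 60):
            rows = algorithm3_fed_score(small_study.sites, server, fed,
                                        chunk_k=k, snp_ids=small_study.snp_ids)
            pv = pvals(rows)
            ids = [r.snp_id for r in rows]
            if base is None:
                base = (ids, pv)
            else:
                assert ids == base[0]
                assert np.allclose(pv, base[1], rtol=1e-9, atol=1e-12,
                                   equal_nan=True)

    def test_single_site_equals_pooled_chunk(self, small_cohort, rng):
        G = rng.integers(0, 3, size=(20, small_cohort.n)).astype(float)
        sites, pooled, Gp = split_cohort(small_cohort, 1, G=G)
        pooled_fit = glmm.fit_null_pooled(pooled)
        server = make_server(pooled.V, backend="mask", seed=8)
        fed = fit_null_federated(sites, server)
        rows_f = algorithm3_fed_score(sites, server, fed, chunk_k=20,
                                      maf_threshold=None)
        rows_p = glmm.score_test_chunk(Gp, pooled_fit.P, pooled_fit.ytilde)
        assert np.allclose(
            [r.score_T for r in rows_f], [r.score_T for r in rows_p],
            rtol=1e-6, atol=1e-6,
        )


class TestFedAlleleStats:
    def test_matches_pooled_af(self, rng):
        from fedglmm.federation import SiteData

        V = np.eye(4)
        mk = lambda sid, lo, hi, G: SiteData(
            site_id=sid, sample_ids=np.arange(lo, hi).astype(str),
            X=np.ones((hi - lo, 1)), y=np.zeros(hi - lo),
            V_block=V[:, lo:hi], G=G,
        )
        sites = [
            mk("site0", 0, 2, np.array([[0.0, 0.0]])),
            mk("site1", 2, 4, np.array([[1.0, 2.0]])),
        ]
        server = make_server(V, backend="mask", seed=9)
        af, keep, imputed = fed_allele_stats(sites, server)
        assert af[0] == pytest.approx(0.375, abs=1e-9)
        assert keep[0]

    def test_rare_variant_filtered(self):
        from fedglmm.federation import SiteData

        n = 100
        V = np.eye(n)
        G = np.zeros((1, n))
        G[0, 0] = 1.0  # af = 0.005
        site = SiteData(site_id="site0", sample_ids=np.arange(n).astype(str),
                        X=np.ones((n, 1)), y=np.zeros(n), V_block=V, G=G)
        server = make_server(V, backend="mask", seed=10)
        af, keep, _ = fed_allele_stats([site], server, maf_threshold=0.01)
        assert af[0] == pytest.approx(0.005, abs=1e-9)
        assert not keep[0]


class TestPrivacySurface:
    def test_transcript_audit_clean(self, fitted_pair):
        """No raw site matrices reach the server; plaintexts are aggregate-level."""
        study, _, fed, server = fitted_pair
        algorithm3_fed_score(study.sites, server, fed, chunk_k=30,
                             snp_ids=study.snp_ids)
        assert audit_transcript(server.transcript) == []
        kinds = {m.kind for m in server.transcript.messages}
        assert not kinds & federation.RAW_KINDS

    def test_transcript_serializes(self, fitted_pair, tmp_path):
        *_, server = fitted_pair
        out = tmp_path / "transcript.jsonl"
        server.transcript.write_jsonl(out)
        import json

        lines = out.read_text().splitlines()
        assert len(lines) == len(server.transcript)
        rec = json.loads(lines[0])
        assert {"sender", "receiver", "kind", "shape", "protected"} <= set(rec)
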