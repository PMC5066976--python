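import copy

import numpy as np
import pytest

from clonalfam.hmm import (
    Cluster,
    HmmError,
    HmmModel,
    build_hmm,
    forward_logprob,
    log_likelihood_ratio,
    partition_logprob,
    viterbi_annotate,
    viterbi_path,
)

from conftest import enumerate_paths, random_hmm


def casino_model(p=0.1):
    """The classic two-state dishonest-casino HMM: a fair die and one
    loaded toward 6, switched with probability p after each roll."""
    fair = np.full(6, 1 / 6)
    loaded = np.array([0.1, 0.1, 0.1, 0.1, 0.1, 0.5])
    trans = np.array([[1 - p, p], [p, 1 - p]])
    # let the game end after any roll with probability 1/2
    trans = trans * 0.5
    end = np.array([0.5, 0.5])
    with np.errstate(divide="ignore"):
        return HmmModel(
            state_names=["fair", "loaded"],
            log_init=np.log([0.5, 0.5]),
            log_trans=np.log(trans),
            log_end=np.log(end),
            log_emit=np.log(np.vstack([fair, loaded])),
            alphabet="123456",
            ambiguous="?",
        )


def factorizing_model():
    """One state, self-transition 1: emissions are i.i.d., so the joint
    probability of k sequences factorizes exactly."""
    with np.errstate(divide="ignore"):
        return HmmModel(
            state_names=["s"],
            log_init=np.log([1.0]),
            log_trans=np.log([[1.0]]),
            log_end=np.log([1.0]),
            log_emit=np.log([[0.25] * 4]),
        )


class TestForwardOracle:
    def test_casino_single_sequence(self):
        model = casino_model()
        lp = forward_logprob(["6646"], model)
        oracle, _ = enumerate_paths(["6646"], model)
        assert lp == pytest.approx(oracle, abs=1e-10)

    def test_casino_pair(self):
        model = casino_model()
        seqs = ["66642", "66642"]
        lp = forward_logprob(seqs, model)
        oracle, _ = enumerate_paths(seqs, model)
        assert lp == pytest.approx(oracle, abs=1e-10)

    def test_casino_viterbi_matches_enumeration(self):
        model = casino_model()
        _, lp = viterbi_path(["66616"], model)
        _, best = enumerate_paths(["66616"], model)
        assert lp == pytest.approx(best, abs=1e-10)

    @pytest.mark.parametrize("seed", range(25))
    def test_random_models_forward_and_viterbi(self, seed):
        """Forward and Viterbi agree with exhaustive path enumeration on
        random small models, single sequences and pairs."""
        rng = np.random.default_rng(1000 + seed)
        model = random_hmm(rng)
        L = int(rng.integers(1, 7))
        k = int(rng.integers(1, 3))
        seqs = ["".join(rng.choice(list(model.alphabet), L)) for _ in range(k)]
        o_sum, o_max = enumerate_paths(seqs, model)
        f = forward_logprob(seqs, model)
        if o_sum == float("-inf"):
            assert f == float("-inf")
            return
        assert f == pytest.approx(o_sum, rel=1e-9, abs=1e-9)
        _, v = viterbi_path(seqs, model)
        assert v == pytest.approx(o_max, rel=1e-9, abs=1e-9)
        assert v <= f + 1e-12

    def test_ambiguous_padding_is_exact_no_op(self):
        model = casino_model()
        base = forward_logprob(["6361"], model)
        assert forward_logprob(["??6361?"], model) == base

    def test_interior_ambiguity_emits_probability_one(self):
        """An interior ambiguous symbol contributes emission factor 1:
        the marginal equals enumeration with that column unconstrained."""
        model = casino_model()
        lp = forward_logprob(["6?1"], model)
        oracle, _ = enumerate_paths(["6?1"], model)
        assert lp == pytest.approx(oracle, abs=1e-10)

    def test_bad_symbol_fatal(self):
        with pytest.raises(HmmError, match="outside alphabet"):
            forward_logprob(["ACGX"], factorizing_model())

    def test_unequal_lengths_fatal(self):
        with pytest.raises(HmmError, match="equal length"):
            forward_logprob(["ACG", "AC"], factorizing_model())


class TestVdjModel:
    def _degenerate_params(self, params, germline, cand):
        """All erosions 0, no insertions, no mutation, usage on one gene
        per region -> the model generates exactly one sequence."""
        p = copy.deepcopy(params)
        for end in p.erosion_dists:
            for g in p.erosion_dists[end]:
                d = np.zeros_like(p.erosion_dists[end][g])
                d[0] = 1.0
                p.erosion_dists[end][g] = d
        for b in p.insertion_len_dists:
            d = np.zeros_like(p.insertion_len_dists[b])
            d[0] = 1.0
            p.insertion_len_dists[b] = d
        for g in p.mut_rates:
            p.mut_rates[g] = np.zeros_like(p.mut_rates[g])
        p.mean_mut = 0.0
        for r, names in cand.items():
            p.gene_usage[r] = {
                n: (1.0 if n in names else 0.0) for n in p.gene_usage[r]
            }
        return p

    def test_degenerate_model_single_sequence(self, params, germline, identity_read):
        read, (v, d, j) = identity_read
        cand = {"V": [v.name], "D": [d.name], "J": [j.name]}
        model = build_hmm(self._degenerate_params(params, germline, cand), germline, cand)
        lp = forward_logprob([read], model)
        # the only free factors are the uniform read-truncation priors on
        # V entry and J exit; the rearrangement itself has probability 1
        assert lp == pytest.approx(np.log(1 / len(v.seq)) + np.log(1 / len(j.seq)), abs=1e-9)
        # any other sequence is impossible
        other = "A" + read[1:] if read[0] != "A" else "C" + read[1:]
        assert forward_logprob([other], model) == float("-inf")

    def test_degenerate_viterbi_annotation(self, params, germline, identity_read):
        read, (v, d, j) = identity_read
        cand = {"V": [v.name], "D": [d.name], "J": [j.name]}
        model = build_hmm(self._degenerate_params(params, germline, cand), germline, cand)
        ann = viterbi_annotate([read], model, germline)
        assert (ann.v_gene, ann.d_gene, ann.j_gene) == (v.name, d.name, j.name)
        assert ann.erosions == (0, 0, 0, 0)
        assert ann.naive_seq == read
        assert ann.logprob == pytest.approx(forward_logprob([read], model), abs=1e-9)
        assert ann.cdr3_start == v.anchor
        assert ann.cdr3_end == len(read) - (len(j.seq) - j.anchor - 3)

    def test_rows_normalize(self, params, germline):
        model = build_hmm(params, germline)  # validate() runs inside
        out = np.exp(model.log_trans).sum(axis=1) + np.exp(model.log_end)
        assert np.allclose(out, 1.0, atol=1e-9)
        assert np.allclose(np.exp(model.log_emit).sum(axis=1), 1.0, atol=1e-9)

    def test_init_mass_follows_gene_usage(self, params, germline):
        p = copy.deepcopy(params)
        v1, v2 = (g.name for g in germline.region_genes("V")[:2])
        p.gene_usage["V"] = {n: 0.0 for n in p.gene_usage["V"]} | {v1: 0.7, v2: 0.3}
        cand = {"V": [v1, v2], "D": germline.names("D"), "J": germline.names("J")}
        model = build_hmm(p, germline, cand)
        init = np.exp(model.log_init)
        mass = {v1: 0.0, v2: 0.0}
        for s, info in enumerate(model.state_info):
            if info[0] == "gl" and info[1] in mass:
                mass[info[1]] += init[s]
        assert mass[v1] == pytest.approx(0.7, abs=1e-9)
        assert mass[v2] == pytest.approx(0.3, abs=1e-9)

    def test_empty_erosion_distribution_fatal(self, params, germline):
        p = copy.deepcopy(params)
        gname = germline.region_genes("V")[0].name
        p.erosion_dists["v_3p"][gname] = np.zeros_like(p.erosion_dists["v_3p"][gname])
        cand = {"V": [gname], "D": germline.names("D"), "J": germline.names("J")}
        with pytest.raises(Exception, match="(?i)erosion|sums"):
            build_hmm(p, germline, cand)

    def test_viterbi_not_above_forward(self, trained_params, germline, small_sample):
        _, records = small_sample
        model = build_hmm(trained_params, germline)
        for rec in records[:10]:
            _, v = viterbi_path([rec.work_seq], model)
            assert v <= forward_logprob([rec.work_seq], model) + 1e-9

    def test_json_round_trip(self, params, germline, identity_read):
        read, (v, d, j) = identity_read
        cand = {"V": [v.name], "D": [d.name], "J": [j.name]}
        model = build_hmm(params, germline, cand)
        again = HmmModel.from_json(model.to_json())
        assert forward_logprob([read], again) == pytest.approx(
            forward_logprob([read], model), abs=1e-9
        )


class TestLikelihoodRatio:
    def test_factorizing_model_ratio_zero(self):
        model = factorizing_model()
        a = Cluster(ids=("a",), seqs=("ACGT",))
        b = Cluster(ids=("b",), seqs=("TTAA",))
        assert log_likelihood_ratio(a, b, model) == pytest.approx(0.0, abs=1e-12)

    def test_clonal_pair_positive(self, trained_params, germline, small_sample):
        rep, records = small_sample
        ev = next(e for e in rep.events if e.n_leaves >= 2)
        model = build_hmm(trained_params, germline)
        recs = {r.id: r for r in records}
        a = Cluster(ids=(ev.leaf_ids[0],), seqs=(recs[ev.leaf_ids[0]].work_seq,), anchor=84)
        b = Cluster(ids=(ev.leaf_ids[1],), seqs=(recs[ev.leaf_ids[1]].work_seq,), anchor=84)
        assert log_likelihood_ratio(a, b, model) > 0

    def test_different_rearrangements_negative(self, trained_params, germline, small_sample):
        rep, records = small_sample
        evs = sorted(rep.events, key=lambda e: e.annotation.cdr3_length or 0)
        e1, e2 = evs[0], evs[-1]
        assert e1.annotation.cdr3_length != e2.annotation.cdr3_length
        recs = {r.id: r for r in records}
        model = build_hmm(trained_params, germline)
        a = Cluster(ids=(e1.leaf_ids[0],), seqs=(recs[e1.leaf_ids[0]].work_seq,),
                    anchor=e1.annotation.cdr3_start)
        b = Cluster(ids=(e2.leaf_ids[0],), seqs=(recs[e2.leaf_ids[0]].work_seq,),
                    anchor=e2.annotation.cdr3_start)
        assert log_likelihood_ratio(a, b, model) < 0

    def test_overlapping_clusters_fatal(self):
        model = factorizing_model()
        a = Cluster(ids=("a", "b"), seqs=("ACGT", "ACGT"))
        b = Cluster(ids=("b",), seqs=("ACGT",))
        with pytest.raises(HmmError, match="overlap"):
            log_likelihood_ratio(a, b, model)

    def test_union_marginal_cached(self):
        model = factorizing_model()
        a = Cluster(ids=("a",), seqs=("ACGT",))
        b = Cluster(ids=("b",), seqs=("TTAA",))
        cache: dict = {}
        log_likelihood_ratio(a, b, model, cache)
        assert cache[("a", "b")] == pytest.approx(
            forward_logprob(["ACGT", "TTAA"], model), abs=1e-12
        )


class TestPartitionLogprob:
    def test_all_singletons_is_sum_of_marginals(self, trained_params, germline, small_sample):
        from clonalfam.clustering import Partition

        _, records = small_sample
        model = build_hmm(trained_params, germline)
        clusters = [Cluster(ids=(r.id,), seqs=(r.work_seq,)) for r in records[:5]]
        total = partition_logprob(Partition(clusters=clusters), model)
        expected = sum(forward_logprob([r.work_seq], model) for r in records[:5])
        assert total == pytest.approx(expected, abs=1e-9)

    def test_merge_changes_total_by_ratio(self, trained_params, germline, small_sample):
        from clonalfam.clustering import Partition

        rep, records = small_sample
        recs = {r.id: r for r in records}
        ev = next(e for e in rep.events if e.n_leaves >= 2)
        model = build_hmm(trained_params, germline)
        a = Cluster(ids=(ev.leaf_ids[0],), seqs=(recs[ev.leaf_ids[0]].work_seq,), anchor=84)
        b = Cluster(ids=(ev.leaf_ids[1],), seqs=(recs[ev.leaf_ids[1]].work_seq,), anchor=84)
        before = partition_logprob(Partition(clusters=[a, b]), model)
        ratio = log_likelihood_ratio(a, b, model)
        ids = tuple(sorted(a.ids + b.ids))
        merged = Cluster(ids=ids, seqs=(recs[ids[0]].work_seq, recs[ids[1]].work_seq))
        after = partition_logprob(Partition(clusters=[merged]), model)
        assert after - before == pytest.approx(ratio, abs=1e-9)

    def test_empty_cluster_fatal(self):
        with pytest.raises(HmmError, match="empty"):
            Cluster(ids=(), seqs=())
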