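"""Batch scoring, screening bookkeeping, reliability, CLI round trip."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import emovocab as ev
from emovocab.cli import main as cli_main

SENTENCE = "he was so angry at me, but sadly there was nothing I could do"


def _padded_sentence(n_tokens=100):
    """The 14-token example padded to n_tokens with covered filler."""
    filler = ("the house was near the river and the garden was green "
              "with trees").split()
    toks = SENTENCE.replace(",", "").lower().split()
    i = 0
    while len(toks) < n_tokens:
        toks.append(filler[i % len(filler)])
        i += 1
    return " ".join(toks)


@pytest.fixture(scope="module")
def small_corpus(resources):
    pop = ev.PopulationConfig(verbosity_mean=300, verbosity_sd=80)
    corpus, _ = ev.generate_corpus(
        pop, resources.lexicon, resources.coverage_vocab,
        n_authors=8, seed=3)
    short = pd.DataFrame({
        "doc_id": ["short1", "short2"],
        "text": ["too short to analyze", "also far too short"],
        "distress": [0.0, 0.0], "wellbeing": [0.0, 0.0],
    })
    return pd.concat([corpus, short], ignore_index=True)


class TestScoreCorpus:
    def test_screening_bookkeeping(self, small_corpus, resources):
        out = ev.score_corpus(small_corpus, resources)
        assert out.n_included == 8
        assert out.n_excluded == 2
        assert set(out.exclusions.doc_id) == {"short1", "short2"}
        assert all("token_count<100" in r for r in out.exclusions.reasons)
        # conservation: inclusions + exclusions = input rows
        assert out.n_included + out.n_excluded == len(small_corpus)
        assert out.metadata["n_input"] == len(small_corpus)

    def test_covariates_carried_through(self, small_corpus, resources):
        out = ev.score_corpus(small_corpus, resources)
        assert "distress" in out.scores.columns
        assert "neg_tone" in out.scores.columns

    def test_padded_example_sentence_rate(self, resources):
        """Each copy of the padded Methods sentence scores 2 unique
        negative lemmas over exactly 100 tokens."""
        text = _padded_sentence(100)
        corpus = pd.DataFrame({
            "doc_id": [f"d{i}" for i in range(5)],
            "text": [text] * 5,
        })
        out = ev.score_corpus(corpus, resources)
        assert (out.scores.token_count == 100).all()
        assert out.scores.neg_ev.tolist() == pytest.approx([2.0] * 5)

    def test_empty_corpus_rejected(self, resources):
        with pytest.raises(ValueError, match="empty corpus"):
            ev.score_corpus(pd.DataFrame(columns=["doc_id", "text"]),
                            resources)

    def test_all_excluded_rejected(self, resources):
        corpus = pd.DataFrame({"doc_id": ["a"], "text": ["too short"]})
        with pytest.raises(ValueError, match="excluded"):
            ev.score_corpus(corpus, resources)

    def test_unreadable_rows_skipped_with_count(self, resources):
        corpus = pd.DataFrame({
            "doc_id": ["ok", "nan_text"],
            "text": [_padded_sentence(120), np.nan],
        })
        out = ev.score_corpus(corpus, resources)
        assert out.n_included == 1
        assert out.metadata["n_unreadable"] == 1

    def test_deterministic_output_bytes(self, small_corpus, resources,
                                        tmp_path):
        cfg = ev.PipelineConfig(seed=9)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        ev.score_corpus(small_corpus, resources, cfg).write(p1)
        ev.score_corpus(small_corpus, resources, cfg).write(p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestSplitHalf:
    def _metric(self, resources):
        return ev.ev_metric(resources.lexicon, "negative")

    def test_self_concatenated_documents_reach_unity(self, resources):
        pop = ev.PopulationConfig(verbosity_mean=150, verbosity_sd=30,
                                  verbosity_min=100,
                                  p_emit_neg=0.05, p_emit_pos=0.05)
        corpus, _ = ev.generate_corpus(
            pop, resources.lexicon, resources.coverage_vocab,
            n_authors=30, seed=4)
        corpus["text"] = corpus.text + " " + corpus.text
        res = ev.split_half_reliability(
            corpus, self._metric(resources), resources,
            ev.PipelineConfig(n_boot=200))
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_independent_halves_near_zero(self, resources):
        pop = ev.PopulationConfig(verbosity_mean=150, verbosity_sd=30,
                                  verbosity_min=100)
        corpus, _ = ev.generate_corpus(
            pop, resources.lexicon, resources.coverage_vocab,
            n_authors=1000, seed=5)
        texts = corpus.text.tolist()
        glued = pd.DataFrame({
            "doc_id": [f"p{i}" for i in range(500)],
            "text": [texts[2 * i] + " " + texts[2 * i + 1]
                     for i in range(500)],
        })
        res = ev.split_half_reliability(
            glued, self._metric(resources), resources,
            ev.PipelineConfig(n_boot=200, rescreen_halves=False))
        assert abs(res.r) < 3 / np.sqrt(res.n)

    def test_latent_stability_yields_positive_reliability(self, resources):
        corpus, _ = ev.generate_corpus(
            ev.PopulationConfig(), resources.lexicon,
            resources.coverage_vocab, n_authors=300, seed=6)
        res = ev.split_half_reliability(
            corpus, self._metric(resources), resources,
            ev.PipelineConfig(n_boot=500))
        assert res.r > 0
        assert res.ci_low > 0

    def test_too_few_documents_rejected(self, resources):
        corpus = pd.DataFrame({
            "doc_id": ["a"], "text": [_padded_sentence(300)]})
        with pytest.raises(ValueError, match=">= 3"):
            ev.split_half_reliability(
                corpus, self._metric(resources), resources)


class TestTestRetest:
    def _scores(self, resources, seed, n=60):
        corpus, truth = ev.generate_corpus(
            ev.PopulationConfig(), resources.lexicon,
            resources.coverage_vocab, n_authors=n, seed=seed)
        return ev.score_corpus(corpus, resources), truth

    def test_identical_waves_give_unity(self, resources):
        s1, _ = self._scores(resources, seed=7)
        res = ev.test_retest(s1, s1, "neg_ev",
                             ev.PipelineConfig(n_boot=200))
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_independent_waves_near_zero(self, resources):
        n = 400
        s1, _ = self._scores(resources, seed=8, n=n)
        s2, _ = self._scores(resources, seed=9, n=n)
        res = ev.test_retest(s1, s2, "neg_ev",
                             ev.PipelineConfig(n_boot=200))
        assert abs(res.r) < 3 / np.sqrt(res.n)

    def test_stable_authors_give_positive_and_larger_r(self, resources):
        """Re-generating wave-2 text from the SAME latent authors yields
        r above 0 and above the independent-authors baseline."""
        pop = ev.PopulationConfig()
        rng = np.random.default_rng(10)
        lex, cov = resources.lexicon, resources.coverage_vocab
        authors = [ev.generate_author(pop, lex, rng, f"a{i}")
                   for i in range(150)]
        waves = []
        for _ in range(2):
            rows = [{"doc_id": a.author_id,
                     "text": ev.generate_document(a, lex, cov, rng)}
                    for a in authors]
            waves.append(ev.score_corpus(pd.DataFrame(rows), resources))
        stable = ev.test_retest(waves[0], waves[1], "neg_ev",
                                ev.PipelineConfig(n_boot=200))
        s1, _ = self._scores(resources, seed=11, n=150)
        s2, _ = self._scores(resources, seed=12, n=150)
        indep = ev.test_retest(s1, s2, "neg_ev",
                               ev.PipelineConfig(n_boot=200))
        assert stable.r > 0
        assert stable.ci_low > 0
        assert stable.r > indep.r

    def test_no_overlap_rejected(self, resources):
        s1, _ = self._scores(resources, seed=13, n=10)
        s2 = ev.CorpusScores(
            scores=s1.scores.assign(
                doc_id=["x" + d for d in s1.scores.doc_id]),
            exclusions=s1.exclusions, metadata=s1.metadata)
        with pytest.raises(ValueError, match="matched pairs"):
            ev.test_retest(s1, s2, "neg_ev")


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = ev.PipelineConfig(min_tokens=50, n_boot=500, seed=4)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        assert ev.PipelineConfig.from_yaml(p) == cfg

    def test_presets(self):
        assert ev.PipelineConfig.preset("study1").n_boot == 2000
        assert ev.PipelineConfig.preset("study2").n_boot == 500
        with pytest.raises(ValueError):
            ev.PipelineConfig.preset("study3")

    def test_config_hash_tracks_content(self):
        a = ev.PipelineConfig()
        b = ev.PipelineConfig(min_tokens=99)
        assert a.config_hash != b.config_hash
        assert a.config_hash == ev.PipelineConfig().config_hash


class TestCLI:
    def test_simulate_score_correlate_round_trip(self, tmp_path):
        runner = CliRunner()
        corpus = tmp_path / "corpus.tsv"
        truth = tmp_path / "truth.tsv"
        r = runner.invoke(cli_main, [
            "simulate", "--n-authors", "30", "--seed", "1",
            "--out-corpus", str(corpus), "--out-truth", str(truth)])
        assert r.exit_code == 0, r.output
        scores = tmp_path / "scores.tsv"
        r = runner.invoke(cli_main, [
            "score", "--corpus", str(corpus), "--out", str(scores)])
        assert r.exit_code == 0, r.output
        assert "produced analyzable texts" in r.output
        r = runner.invoke(cli_main, [
            "correlate", "--scores", str(scores),
            "--x", "neg_ev", "--y", "distress",
            "--controls", "open_class_ttr,neg_tone,pos_tone",
            "--preset", "study2", "--seed", "2"])
        assert r.exit_code == 0, r.output
        assert "BCa CI" in r.output

    def test_score_errors_exit_nonzero(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("doc_id\ttext\na\ttoo short\n")
        runner = CliRunner()
        r = runner.invoke(cli_main, [
            "score", "--corpus", str(bad),
            "--out", str(tmp_path / "o.tsv")])
        assert r.exit_code != 0
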