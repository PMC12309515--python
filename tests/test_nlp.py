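"""NLP pipeline: sectioning, tagging, co-occurrence graph, random-walk
ranking, lexicon mapping and the 11-feature extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctsurveil import nlp
from ctsurveil.nlp import (
    CLUSTER_NAMES,
    ConceptLexicon,
    NLPConfig,
    build_cooccurrence_graph,
    extract_keyphrases,
    featurize_report,
    map_phrase_to_cluster,
    rank_terms,
    segment_report,
    tokenize_and_tag,
)


class TestSegmentation:
    def test_headers_split_sections(self):
        rep = segment_report("INDICATION: annual surveillance. FINDINGS: stable.")
        assert rep.sections["indication_history"] == "annual surveillance."
        assert rep.sections["findings"] == "stable."

    def test_headerless_text_goes_unassigned(self):
        rep = segment_report("completely free text without any headers")
        assert list(rep.sections) == ["unassigned"]

    def test_duplicate_headers_concatenate_in_order(self):
        rep = segment_report("FINDINGS: first part. FINDINGS: second part.")
        assert rep.sections["findings"] == "first part.\nsecond part."

    def test_aliases_case_insensitive(self):
        rep = segment_report("history: prior cancer. Impression: stable nodule.")
        assert "prior cancer" in rep.sections["indication_history"]
        assert "stable nodule" in rep.sections["impression"]


class TestTokenization:
    def test_token_count_includes_terminator(self):
        rep = segment_report("FINDINGS: Stable nodule.")
        tokens = tokenize_and_tag(rep)
        assert len(tokens) == 3
        assert {t.sentence_index for t in tokens} == {0}

    def test_two_sentences_get_distinct_indices(self):
        rep = segment_report("FINDINGS: One nodule. Two nodules.")
        tokens = tokenize_and_tag(rep)
        assert {t.sentence_index for t in tokens} == {0, 1}

    def test_empty_section_yields_no_tokens(self):
        rep = segment_report("FINDINGS:   ")
        assert tokenize_and_tag(rep) == []

    def test_coarse_pos_tags(self):
        rep = segment_report("FINDINGS: The stable nodule shows metastatic change.")
        tags = {t.text.lower(): t.pos for t in tokenize_and_tag(rep)}
        assert tags["the"] == "OTHER"
        assert tags["stable"] == "ADJ"
        assert tags["nodule"] == "NOUN"
        assert tags["shows"] == "VERB"
        assert tags["metastatic"] == "ADJ"


def _brute_force_pairs(tokens, window, stoplist=nlp.DEFAULT_STOPLIST):
    """Independent O(n^2) enumeration of in-window candidate pairs."""
    from collections import Counter

    counts = Counter()
    sentences = {}
    for tok in tokens:
        if tok.is_word:
            sentences.setdefault(tok.sentence_index, []).append(tok)
    for sent in sentences.values():
        for i in range(len(sent)):
            for j in range(i + 1, len(sent)):
                if j - i >= window:
                    continue
                a, b = sent[i], sent[j]
                if not (nlp._is_candidate(a, stoplist) and nlp._is_candidate(b, stoplist)):
                    continue
                if a.stem == b.stem:
                    continue
                counts[tuple(sorted((a.stem, b.stem)))] += 1
    return dict(counts)


class TestCooccurrenceGraph:
    def test_three_candidates_window_three(self):
        rep = segment_report("FINDINGS: annual surveillance CT")
        tokens = tokenize_and_tag(rep)
        g = build_cooccurrence_graph(tokens, window=3)
        edges = {tuple(sorted(e)): d["weight"] for *e, d in g.edges(data=True)}
        assert edges == {
            ("annual", "ct"): 1,
            ("annual", "surveillance"): 1,
            ("ct", "surveillance"): 1,
        }

    def test_no_candidates_empty_graph(self):
        rep = segment_report("FINDINGS: is was and the of")
        g = build_cooccurrence_graph(tokenize_and_tag(rep))
        assert g.number_of_nodes() == 0

    def test_window_below_two_rejected(self):
        with pytest.raises(ValueError):
            build_cooccurrence_graph([], window=1)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(
        st.sampled_from(["nodule", "cough", "stable", "the", "lung", "mass",
                         "is", "effusion", "pleural", "annual", "."]),
        min_size=0, max_size=60,
    ), st.integers(min_value=2, max_value=5))
    def test_matches_brute_force_enumeration(self, words, window):
        rep = segment_report("FINDINGS: " + " ".join(words))
        tokens = tokenize_and_tag(rep)
        g = build_cooccurrence_graph(tokens, window=window)
        got = {tuple(sorted(e)): d["weight"] for *e, d in g.edges(data=True)}
        assert got == _brute_force_pairs(tokens, window)


def _oracle_stationary(graph, damping, n_iter=5000):
    """Dense-matrix power iteration on the damped walk, written independently
    of the implementation under test."""
    nodes = sorted(graph.nodes)
    n = len(nodes)
    W = np.zeros((n, n))
    for u, v, d in graph.edges(data=True):
        i, j = nodes.index(u), nodes.index(v)
        W[i, j] = W[j, i] = d.get("weight", 1.0)
    col = W.sum(axis=0)
    P = np.zeros((n, n))
    for j in range(n):
        P[:, j] = W[:, j] / col[j] if col[j] > 0 else 1.0 / n
    G = (1 - damping) / n * np.ones((n, n)) + damping * P
    s = np.full(n, 1.0 / n)
    for _ in range(n_iter):
        s = G @ s
    return dict(zip(nodes, s / s.sum()))


class TestRandomWalkRanking:
    def test_two_nodes_one_edge_symmetric(self):
        import networkx as nx

        g = nx.Graph()
        g.add_edge("a", "b", weight=3)
        scores = rank_terms(g)
        assert scores["a"] == pytest.approx(0.5, abs=1e-9)
        assert scores["b"] == pytest.approx(0.5, abs=1e-9)

    def test_single_isolated_node_scores_one(self):
        import networkx as nx

        g = nx.Graph()
        g.add_node("solo")
        assert rank_terms(g)["solo"] == pytest.approx(1.0)

    def test_matches_dense_power_iteration_oracle(self):
        import networkx as nx

        rng = np.random.default_rng(7)
        for trial in range(100):
            n = int(rng.integers(2, 13))
            g = nx.Graph()
            g.add_nodes_from(f"n{i}" for i in range(n))
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.4:
                        g.add_edge(f"n{i}", f"n{j}", weight=int(rng.integers(1, 5)))
            scores = rank_terms(g, tol=1e-14, max_iter=10000)
            oracle = _oracle_stationary(g, damping=0.85)
            assert sum(scores.values()) == pytest.approx(1.0, abs=1e-9)
            for node in oracle:
                assert scores[node] == pytest.approx(oracle[node], abs=1e-8)

    def test_scores_nonnegative_and_sum_one(self, small_study):
        cfg = NLPConfig()
        for rep in small_study.reports[:20]:
            sec = segment_report(rep["text"])
            toks = tokenize_and_tag(sec)
            g = build_cooccurrence_graph(toks)
            scores = rank_terms(g)
            if scores:
                assert min(scores.values()) >= 0
                assert sum(scores.values()) == pytest.approx(1.0, abs=1e-9)


class TestLexicon:
    def test_named_cluster_examples(self):
        lex = ConceptLexicon.default()
        assert map_phrase_to_cluster("surveillance", lex) == "surveillance"
        assert map_phrase_to_cluster("chest pain", lex) == "symptoms"
        assert map_phrase_to_cluster("xyzzy", lex) is None

    def test_stemmed_variants_match(self):
        lex = ConceptLexicon.default()
        assert map_phrase_to_cluster("screenings", lex) == "surveillance"
        assert map_phrase_to_cluster("pulmonary metastases", lex) == "metastasis"

    def test_overlapping_seed_sets_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            ConceptLexicon(clusters={"surveillance": ["cough"], "symptoms": ["cough"]})

    def test_priority_resolves_multi_cluster_phrases(self):
        lex = ConceptLexicon.default()
        # contains both a surveillance and a follow-up seed; surveillance wins
        assert map_phrase_to_cluster("surveillance follow-up", lex) == "surveillance"


class TestFeaturize:
    def test_phrase_counted_with_multiplicity(self):
        text = ("INDICATION: Annual follow-up imaging of a known nodule. "
                "Recommend follow-up imaging in one year.\n"
                "FINDINGS: The lungs are clear.")
        vec = featurize_report(text, config=NLPConfig().lossless()).as_dict()
        assert vec["kp_follow_up"] == 2.0

    def test_empty_report_all_zero(self):
        vec = featurize_report("", config=NLPConfig())
        assert np.allclose(vec.values, 0.0)

    def test_vector_has_eleven_versioned_entries(self):
        vec = featurize_report("FINDINGS: clear lungs.", config=NLPConfig())
        assert len(vec.values) == 11
        assert vec.names == nlp.FEATURE_NAMES

    def test_counts_match_set_membership_oracle(self):
        """Cluster counts equal an independent regex/set-membership count over
        the extracted phrase list."""
        lex = ConceptLexicon.default()
        cfg = NLPConfig().lossless()
        text = ("INDICATION: Routine surveillance imaging of the chest. "
                "chest pain with acute onset is reported.\n"
                "FINDINGS: No osseous metastasis is seen. The lungs are clear.\n"
                "IMPRESSION: Concern for local recurrence of disease.")
        sec = segment_report(text)
        toks = tokenize_and_tag(sec)
        g = build_cooccurrence_graph(toks)
        scores = rank_terms(g)
        phrases = extract_keyphrases(toks, scores, top_fraction=1.0)
        oracle = {c: 0 for c in CLUSTER_NAMES}
        for ph in phrases:
            cl = map_phrase_to_cluster(ph, lex)
            if cl:
                oracle[cl] += ph.count
        vec = featurize_report(text, lex, cfg).as_dict()
        for c in CLUSTER_NAMES:
            assert vec[f"kp_{c}"] == oracle[c]
        assert oracle["surveillance"] == 1
        assert oracle["symptoms"] == 1
        assert oracle["metastasis"] == 1
        assert oracle["recurrence"] == 1

    def test_section_restricted_binaries(self):
        text = ("INDICATION: Routine surveillance imaging of the chest.\n"
                "FINDINGS: cough with acute onset is reported.")
        vec = featurize_report(text, config=NLPConfig()).as_dict()
        assert vec["surveillance_in_history"] == 1.0
        assert vec["symptoms_in_history"] == 0.0  # cough sits in findings

    def test_deterministic(self):
        text = "INDICATION: Routine surveillance imaging of the chest.\nFINDINGS: clear."
        v1 = featurize_report(text, config=NLPConfig())
        v2 = featurize_report(text, config=NLPConfig())
        assert np.array_equal(v1.values, v2.values)

    def test_appending_surveillance_sentence_is_monotone(self):
        base = ("INDICATION: Routine surveillance imaging of the chest.\n"
                "FINDINGS: The lungs are clear. No suspicious nodule is identified.")
        extra = " This is a surveillance chest examination."
        for cfg in (NLPConfig(), NLPConfig().lossless()):
            v0 = featurize_report(base, config=cfg).as_dict()["kp_surveillance"]
            v1 = featurize_report(base + extra, config=cfg).as_dict()["kp_surveillance"]
            assert v1 >= v0

    def test_rendered_counts_recovered_exactly_lossless(self, rng):
        """Rendering then lossless featurization is the identity on the
        injected per-cluster phrase counts."""
        from ctsurveil.synthetic import CTEvent, GeneratorConfig, render_report

        cfg = GeneratorConfig(n_patients=1)
        lex = ConceptLexicon.default()
        ncfg = NLPConfig().lossless()
        for i in range(150):
            ind = "surveillance" if i % 2 else "other"
            rendered = render_report(CTEvent("P", 0.0, ind), cfg, rng)
            vec = featurize_report(rendered.text, lex, ncfg).as_dict()
            for c in CLUSTER_NAMES:
                assert vec[f"kp_{c}"] == float(rendered.phrase_counts[c]), rendered.text
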