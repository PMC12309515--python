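"""Six-step NLP pipeline turning a free-text chest-CT report into concept features.

The pipeline is: (1) section segmentation, (2) sentence/word tokenization,
(3) coarse part-of-speech tagging, (4) graph-based key-phrase ranking via a
damped random walk over a word co-occurrence graph, (5) assignment of key
phrases to oncology concept clusters through a curated stemmed lexicon, and
(6) frequency-based feature extraction (11 numeric features per report).

Tokenization, sentence splitting, POS tagging and stemming are small
deterministic rule-based components: radiology reports are short, templated
documents and the downstream features only need a coarse NOUN/ADJ/VERB/OTHER
distinction to select key-phrase candidates.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import yaml

__all__ = [
    "SectionedReport",
    "TaggedToken",
    "KeyPhrase",
    "ConceptLexicon",
    "NLPConfig",
    "NLPFeatureVector",
    "DEFAULT_LEXICON",
    "CLUSTER_NAMES",
    "FEATURE_NAMES",
    "light_stem",
    "segment_report",
    "tokenize_and_tag",
    "build_cooccurrence_graph",
    "rank_terms",
    "extract_keyphrases",
    "rank_keyphrases",
    "map_phrase_to_cluster",
    "featurize_report",
]

SECTION_NAMES = (
    "indication_history",
    "technique",
    "comparison",
    "findings",
    "impression",
    "unassigned",
)

#: canonical concept clusters, in lexicon priority order (earlier wins ties)
CLUSTER_NAMES = (
    "surveillance",
    "follow_up",
    "symptoms",
    "recurrence",
    "metastasis",
    "treatment",
    "medication",
)

DEFAULT_SECTION_ALIASES = {
    "indication": "indication_history",
    "history": "indication_history",
    "clinical history": "indication_history",
    "clinical indication": "indication_history",
    "reason for exam": "indication_history",
    "technique": "technique",
    "protocol": "technique",
    "comparison": "comparison",
    "findings": "findings",
    "finding": "findings",
    "impression": "impression",
    "conclusion": "impression",
}

DEFAULT_LEXICON = {
    "surveillance": ["surveillance", "screening"],
    "follow_up": ["follow-up", "followup"],
    "symptoms": [
        "cough",
        "chest pain",
        "dyspnea",
        "hemoptysis",
        "fever",
        "weight loss",
        "fatigue",
        "wheezing",
    ],
    "recurrence": ["recurrence", "recurrent"],
    "metastasis": ["metastasis", "metastases", "metastatic"],
    "treatment": ["chemotherapy", "radiation", "resection", "lobectomy", "radiotherapy"],
    "medication": ["erlotinib", "carboplatin", "paclitaxel", "pembrolizumab", "gefitinib"],
}

DEFAULT_LEXICON_VERSION = "default-1"

DEFAULT_STOPLIST = frozenset({"patient", "exam", "examination", "study", "report"})

#: fixed, versioned feature order of the 11-entry NLP feature vector
FEATURE_NAMES = tuple(f"kp_{c}" for c in CLUSTER_NAMES) + (
    "surveillance_in_history",
    "symptoms_in_history",
    "comparison_present",
    "keyphrase_density",
)
FEATURE_VERSION = "nlp-11-v1"

_FUNCTION_WORDS = frozenset(
    """a an the of in on at by to for with without and or nor but is are was were be
    been being there this that these those it its as from than then since if so no
    not any all both each either other some such do does did has have had can could
    should would will may might must per versus vs about into over under again more
    most same own s t don now he she they we you i his her their our your up down out
    off once only very too just because while during before after above below between
    through against further here when where why how which who whom what am""".split()
)

_VERB_WORDS = frozenset(
    """demonstrate demonstrates demonstrated show shows showed shown reveal reveals
    revealed recommend recommends recommended perform performs performed obtained
    obtain compare compared noted seen identified visualized presents presented
    reports reported denies denied underwent received given undergo receives remains
    remain appears appear measures measuring measured suggest suggests suggested
    evaluate evaluated made see note request requested""".split()
)

_ADJ_WORDS = frozenset(
    """annual stable new suspicious mild moderate severe bilateral right left
    unremarkable normal abnormal clear small large prior previous acute chronic
    routine focal diffuse low high enlarged calcified solid subsolid tiny
    interval""".split()
)

_ADJ_SUFFIXES = ("ous", "ary", "ic", "ive", "less", "able", "ible", "al", "ar")

_WORD_RE = re.compile(r"[A-Za-z][A-Za-z'-]*|\d+(?:\.\d+)?|[^\sA-Za-z\d]")
_SENT_SPLIT_RE = re.compile(r"(?<=[.!?;])\s+")


def light_stem(word: str) -> str:
    """Strip common inflectional suffixes (plural, then participle) from a
    lowercased word."""
    w = word.lower()
    if len(w) > 4 and w.endswith("es"):
        w = w[:-2]
    elif len(w) > 3 and w.endswith("s") and not w.endswith("ss"):
        w = w[:-1]
    if len(w) > 5 and w.endswith("ing"):
        w = w[:-3]
    elif len(w) > 4 and w.endswith("ed"):
        w = w[:-2]
    return w


# ---------------------------------------------------------------------------
# step 1: segmentation


@dataclass
class SectionedReport:
    report_id: str
    sections: dict[str, str] = field(default_factory=dict)

    def text(self, name: str) -> str:
        return self.sections.get(name, "")


def _alias_pattern(aliases: dict[str, str]) -> re.Pattern:
    keys = sorted(aliases, key=len, reverse=True)
    joined = "|".join(re.escape(k) for k in keys)
    return re.compile(rf"(?i)(?:(?<=^)|(?<=[\s\n]))({joined})\s*:", re.MULTILINE)


def segment_report(
    text: str,
    report_id: str = "",
    aliases: dict[str, str] | None = None,
) -> SectionedReport:
    """Split a report into canonical sections via a case-insensitive header table.

    Text preceding the first recognized header goes to ``unassigned``; repeated
    headers for the same canonical section are concatenated in order.
    """
    if text is None:
        raise ValueError("report text must not be None")
    aliases = {k.lower(): v for k, v in (aliases or DEFAULT_SECTION_ALIASES).items()}
    pattern = _alias_pattern(aliases)
    sections: dict[str, list[str]] = {}
    matches = list(pattern.finditer(text))
    if not matches or matches[0].start() > 0:
        head = text[: matches[0].start()] if matches else text
        if head.strip():
            sections.setdefault("unassigned", []).append(head.strip())
    for i, m in enumerate(matches):
        name = aliases[m.group(1).lower()]
        end = matches[i + 1].start() if i + 1 < len(matches) else len(text)
        body = text[m.end(): end].strip()
        sections.setdefault(name, []).append(body)
    return SectionedReport(
        report_id=report_id,
        sections={k: "\n".join(v) for k, v in sections.items()},
    )


# ---------------------------------------------------------------------------
# steps 2-3: tokenization and coarse POS tagging


@dataclass
class TaggedToken:
    text: str
    pos: str  # NOUN | ADJ | VERB | OTHER
    sentence_index: int
    section: str

    @property
    def is_word(self) -> bool:
        return self.text[0].isalpha()

    @property
    def stem(self) -> str:
        return light_stem(self.text)


def _tag_word(word: str) -> str:
    w = word.lower()
    if w in _FUNCTION_WORDS:
        return "OTHER"
    if w in _ADJ_WORDS:
        return "ADJ"
    if w in _VERB_WORDS:
        return "VERB"
    if any(w.endswith(s) for s in _ADJ_SUFFIXES) and len(w) > 4:
        return "ADJ"
    return "NOUN"


def tokenize_and_tag(report: SectionedReport) -> list[TaggedToken]:
    """Sentence-split then word-tokenize every section; sentence indices are
    global and non-decreasing over the canonical section order."""
    tokens: list[TaggedToken] = []
    sent_idx = 0
    for section in SECTION_NAMES:
        body = report.sections.get(section, "")
        if not body.strip():
            continue
        for sentence in _SENT_SPLIT_RE.split(body.strip()):
            if not sentence.strip():
                continue
            any_token = False
            for m in _WORD_RE.finditer(sentence):
                tok = m.group(0)
                if tok[0].isalpha():
                    pos = _tag_word(tok)
                elif tok[0].isdigit():
                    pos = "OTHER"
                else:
                    pos = "OTHER"
                tokens.append(TaggedToken(tok, pos, sent_idx, section))
                any_token = True
            if any_token:
                sent_idx += 1
    return tokens


# ---------------------------------------------------------------------------
# step 4: co-occurrence graph and damped random-walk ranking


def _is_candidate(tok: TaggedToken, stoplist: frozenset[str]) -> bool:
    return (
        tok.is_word
        and tok.pos in ("NOUN", "ADJ")
        and tok.text.lower() not in stoplist
        and tok.stem not in stoplist
        and len(tok.text) > 1
    )


def build_cooccurrence_graph(
    tokens: list[TaggedToken],
    window: int = 3,
    stoplist: frozenset[str] = DEFAULT_STOPLIST,
) -> nx.Graph:
    """Undirected weighted graph over candidate-term stems.

    An edge accumulates one unit of weight each time two distinct candidate
    terms co-occur within ``window`` word positions inside one sentence.
    """
    if window < 2:
        raise ValueError(f"co-occurrence window must be >= 2, got {window}")
    graph = nx.Graph()
    # group word tokens by sentence, positions counted over word tokens only
    sentences: dict[int, list[TaggedToken]] = {}
    for tok in tokens:
        if tok.is_word:
            sentences.setdefault(tok.sentence_index, []).append(tok)
    for sent in sentences.values():
        cand = [(i, tok) for i, tok in enumerate(sent) if _is_candidate(tok, stoplist)]
        for node_tok in cand:
            graph.add_node(node_tok[1].stem)
        for a in range(len(cand)):
            i, ti = cand[a]
            for b in range(a + 1, len(cand)):
                j, tj = cand[b]
                if j - i >= window:
                    break
                u, v = ti.stem, tj.stem
                if u == v:
                    continue
                w = graph.get_edge_data(u, v, {}).get("weight", 0)
                graph.add_edge(u, v, weight=w + 1)
    return graph


def rank_terms(
    graph: nx.Graph,
    damping: float = 0.85,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> dict[str, float]:
    """Stationary scores of the damped weighted random walk on the term graph.

    Scores are non-negative and sum to one. Nodes without edges receive only
    teleport mass (their walk mass is redistributed uniformly). On failure to
    converge within ``max_iter`` the best iterate is returned with a warning.
    """
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        return {}
    index = {u: k for k, u in enumerate(nodes)}
    strength = np.zeros(n)
    rows, cols, vals = [], [], []
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        iu, iv = index[u], index[v]
        rows += [iu, iv]
        cols += [iv, iu]
        vals += [w, w]
        strength[iu] += w
        strength[iv] += w
    s = np.full(n, 1.0 / n)
    dangling = strength == 0
    if rows:
        from scipy.sparse import csr_matrix

        adj = csr_matrix((vals, (rows, cols)), shape=(n, n))
    else:
        adj = None
    converged = False
    for _ in range(max_iter):
        if adj is not None:
            out = s / np.where(strength > 0, strength, 1.0)
            out[dangling] = 0.0
            walk = adj.T @ out
        else:
            walk = np.zeros(n)
        walk = walk + s[dangling].sum() / n
        s_new = (1.0 - damping) / n + damping * walk
        if np.abs(s_new - s).sum() < tol:
            s = s_new
            converged = True
            break
        s = s_new
    if not converged:
        warnings.warn(
            f"random-walk ranking did not converge in {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    s = s / s.sum()
    return {u: float(s[index[u]]) for u in nodes}


@dataclass
class KeyPhrase:
    text: str
    terms: tuple[str, ...]  # stemmed member terms, adjacent in source
    score: float  # mean member score, in [0, 1]
    cluster: str | None
    count: int  # occurrences in the report


def extract_keyphrases(
    tokens: list[TaggedToken],
    scores: dict[str, float],
    stoplist: frozenset[str] = DEFAULT_STOPLIST,
    top_fraction: float = 0.25,
    max_phrase_len: int = 3,
) -> list[KeyPhrase]:
    """Merge adjacent top-ranked candidate terms into phrases of 1-3 terms.

    Terms qualify when their walk score reaches the ``1 - top_fraction``
    quantile of the score distribution (ties included; at least one term
    always qualifies). Runs longer than ``max_phrase_len`` are chunked
    greedily. Phrases are returned with report-level occurrence counts,
    ordered by descending score then lexicographically.
    """
    if not tokens or not scores:
        return []
    values = np.array(sorted(scores.values()))
    if top_fraction >= 1.0:
        threshold = -np.inf
    else:
        threshold = float(np.quantile(values, 1.0 - top_fraction))
    top = {t for t, sc in scores.items() if sc >= threshold}
    if not top:
        top = {max(scores, key=lambda t: (scores[t], t))}

    sentences: dict[int, list[TaggedToken]] = {}
    for tok in tokens:
        if tok.is_word:
            sentences.setdefault(tok.sentence_index, []).append(tok)

    found: dict[tuple[str, ...], KeyPhrase] = {}
    for sent in sentences.values():
        run: list[TaggedToken] = []
        for tok in sent + [None]:  # sentinel flushes the last run
            if tok is not None and _is_candidate(tok, stoplist) and tok.stem in top:
                run.append(tok)
                continue
            for start in range(0, len(run), max_phrase_len):
                chunk = run[start: start + max_phrase_len]
                if not chunk:
                    continue
                terms = tuple(t.stem for t in chunk)
                if terms in found:
                    found[terms].count += 1
                else:
                    found[terms] = KeyPhrase(
                        text=" ".join(t.text.lower() for t in chunk),
                        terms=terms,
                        score=float(np.mean([scores[t] for t in terms])),
                        cluster=None,
                        count=1,
                    )
            run = []
    return sorted(found.values(), key=lambda p: (-p.score, p.terms))


def rank_keyphrases(
    graph: nx.Graph,
    tokens: list[TaggedToken],
    damping: float = 0.85,
    tol: float = 1e-6,
    max_iter: int = 100,
    stoplist: frozenset[str] = DEFAULT_STOPLIST,
    top_fraction: float = 0.25,
    max_phrase_len: int = 3,
) -> tuple[dict[str, float], list[KeyPhrase]]:
    scores = rank_terms(graph, damping=damping, tol=tol, max_iter=max_iter)
    phrases = extract_keyphrases(
        tokens, scores, stoplist=stoplist,
        top_fraction=top_fraction, max_phrase_len=max_phrase_len,
    )
    return scores, phrases


# ---------------------------------------------------------------------------
# step 5: concept-cluster lexicon


@dataclass
class ConceptLexicon:
    """Curated cluster -> seed phrase sets with a deterministic priority order."""

    clusters: dict[str, list[str]]
    version: str = DEFAULT_LEXICON_VERSION
    priority: tuple[str, ...] = CLUSTER_NAMES

    def __post_init__(self) -> None:
        unknown = set(self.clusters) - set(self.priority)
        if unknown:
            raise ValueError(f"clusters missing from priority order: {sorted(unknown)}")
        self._stemmed: dict[str, list[tuple[str, ...]]] = {}
        seen: dict[tuple[str, ...], str] = {}
        for cluster in self.priority:
            seeds = self.clusters.get(cluster, [])
            stemmed = []
            for seed in seeds:
                key = tuple(light_stem(w) for w in re.findall(r"[A-Za-z'-]+", seed.lower()))
                if not key:
                    raise ValueError(f"empty seed phrase in cluster {cluster!r}")
                if key in seen and seen[key] != cluster:
                    raise ValueError(
                        f"seed {seed!r} maps to both {seen[key]!r} and {cluster!r} "
                        "after stemming; cluster seed sets must be disjoint"
                    )
                seen[key] = cluster
                stemmed.append(key)
            self._stemmed[cluster] = stemmed

    def stemmed_seeds(self, cluster: str) -> list[tuple[str, ...]]:
        return self._stemmed.get(cluster, [])

    @classmethod
    def default(cls) -> "ConceptLexicon":
        return cls(clusters={k: list(v) for k, v in DEFAULT_LEXICON.items()})

    @classmethod
    def from_file(cls, path) -> "ConceptLexicon":
        with open(path) as fh:
            raw = yaml.safe_load(fh) if str(path).endswith((".yml", ".yaml")) else json.load(fh)
        version = raw.pop("version", "unversioned") if isinstance(raw, dict) else "unversioned"
        return cls(clusters=raw, version=version)

    def to_dict(self) -> dict:
        out = {k: list(v) for k, v in self.clusters.items()}
        out["version"] = self.version
        return out


def _contains_seq(haystack: tuple[str, ...], needle: tuple[str, ...]) -> bool:
    n = len(needle)
    return any(haystack[i: i + n] == needle for i in range(len(haystack) - n + 1))


def map_phrase_to_cluster(phrase, lexicon: ConceptLexicon) -> str | None:
    """Assign a phrase to the first cluster (priority order) whose stemmed seed
    occurs as a contiguous subsequence of the phrase's stemmed terms."""
    if isinstance(phrase, KeyPhrase):
        terms = phrase.terms
    else:
        terms = tuple(light_stem(w) for w in re.findall(r"[A-Za-z'-]+", str(phrase).lower()))
    for cluster in lexicon.priority:
        for seed in lexicon.stemmed_seeds(cluster):
            if _contains_seq(terms, seed):
                return cluster
    return None


# ---------------------------------------------------------------------------
# step 6: frequency-based feature extraction


@dataclass
class NLPConfig:
    window: int = 3
    damping: float = 0.85
    tol: float = 1e-6
    max_iter: int = 100
    top_fraction: float = 0.25
    max_phrase_len: int = 3
    stoplist: frozenset[str] = DEFAULT_STOPLIST
    section_aliases: dict[str, str] | None = None

    def lossless(self) -> "NLPConfig":
        """Variant retaining every candidate term (no salience filtering)."""
        return replace(self, top_fraction=1.0)


@dataclass
class NLPFeatureVector:
    report_id: str
    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES
    version: str = FEATURE_VERSION

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def _section_has_cluster(tokens, section, cluster, lexicon):
    stems = tuple(t.stem for t in tokens if t.section == section and t.is_word)
    return any(
        _contains_seq(stems, seed) for seed in lexicon.stemmed_seeds(cluster)
    )


def _comparison_present(sectioned: SectionedReport) -> int:
    body = sectioned.sections.get("comparison", "").strip().lower()
    if not body:
        return 0
    if re.match(r"^(none|no prior|no previous|not available)\b", body):
        return 0
    return 1


def featurize_report(
    report,
    lexicon: ConceptLexicon | None = None,
    config: NLPConfig | None = None,
) -> NLPFeatureVector:
    """Run the full pipeline on one report and emit the 11-entry feature vector.

    ``report`` may be raw text, a ``(report_id, text)`` pair, or any object
    with ``report_id`` and ``text`` attributes.
    """
    lexicon = lexicon or ConceptLexicon.default()
    config = config or NLPConfig()
    if isinstance(report, str):
        report_id, text = "", report
    elif isinstance(report, tuple):
        report_id, text = report
    else:
        report_id, text = report.report_id, report.text

    sectioned = segment_report(text, report_id=report_id, aliases=config.section_aliases)
    tokens = tokenize_and_tag(sectioned)
    graph = build_cooccurrence_graph(tokens, window=config.window, stoplist=config.stoplist)
    _, phrases = rank_keyphrases(
        graph,
        tokens,
        damping=config.damping,
        tol=config.tol,
        max_iter=config.max_iter,
        stoplist=config.stoplist,
        top_fraction=config.top_fraction,
        max_phrase_len=config.max_phrase_len,
    )

    counts = {c: 0.0 for c in CLUSTER_NAMES}
    total_occurrences = 0
    for phrase in phrases:
        phrase.cluster = map_phrase_to_cluster(phrase, lexicon)
        total_occurrences += phrase.count
        if phrase.cluster is not None:
            counts[phrase.cluster] += phrase.count

    n_words = sum(1 for t in tokens if t.is_word)
    density = 100.0 * total_occurrences / n_words if n_words else 0.0

    values = np.array(
        [counts[c] for c in CLUSTER_NAMES]
        + [
            float(_section_has_cluster(tokens, "indication_history", "surveillance", lexicon)),
            float(_section_has_cluster(tokens, "indication_history", "symptoms", lexicon)),
            float(_comparison_present(sectioned)),
            density,
        ]
    )
    return NLPFeatureVector(report_id=report_id, values=values)
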