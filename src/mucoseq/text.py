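"""Quantitative text analysis of per-gene functional annotation text.

Documents are tokenised keeping punctuation as separate tokens,
lowercased and lemmatised with a dictionary lookup; stopwords (standard
plus a custom list of words common in protein annotation) are replaced
by empty pads so that word adjacency is preserved — a bigram never spans
a removed word.  Keyness between a target and a reference group is the
signed chi-square statistic with Yates continuity correction; bigram
collocations are scored by the log odds ratio of the 2x2 adjacency
table and its Wald z statistic.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

PAD = ""

# words and hyphen/apostrophe/slash-joined words, else single punctuation marks
_TOKEN_RE = re.compile(r"\w+(?:[-'/]\w+)*|[^\w\s]")

#: words common in protein functional annotation, removed on top of the
#: standard stopword list (extensible by the caller)
DEFAULT_CUSTOM_STOPWORDS = (
    "act",
    "however",
    "isoform",
    "mediate",
    "play",
    "resulting",
    "target",
    "involve",
    "may",
    "also",
    "via",
    "role",
    "process",
    "protein",
    "gene",
    "function",
)


def _is_punct(token: str) -> bool:
    return bool(token) and not any(ch.isalnum() for ch in token)


@dataclass
class TextCorpus:
    """Tokenised, lemmatised, pad-preserving documents with group labels.

    ``documents`` maps gene id -> ordered token list where removed
    stopwords are empty-string pads; ``groups`` maps gene id -> group
    label.  Pads and punctuation are never counted as tokens but keep
    their positions so adjacency is meaningful.
    """

    documents: dict = field(default_factory=dict)
    groups: dict = field(default_factory=dict)

    def countable_tokens(self, gene) -> list:
        return [t for t in self.documents[gene] if t != PAD and not _is_punct(t)]

    def total_tokens(self) -> int:
        return sum(len(self.countable_tokens(g)) for g in self.documents)


def tokenize(text: str) -> list:
    """Split into lowercase word and punctuation tokens."""
    return [t.lower() for t in _TOKEN_RE.findall(text)]


def build_corpus(
    gene_text: dict | pd.Series,
    groups: dict | pd.Series,
    lemma_dict: dict | None = None,
    stopwords=(),
    custom_stopwords=DEFAULT_CUSTOM_STOPWORDS,
) -> TextCorpus:
    """Build a pad-preserving corpus from per-gene annotation text.

    ``gene_text`` maps gene id -> raw text; ``groups`` maps gene id ->
    group label and defines which genes enter the corpus (genes without
    a text record are logged and skipped).  Lemmatisation is a
    dictionary lookup with identity fallback; stopword matching is
    case-insensitive and applied AFTER lemmatisation so an inflected
    form whose lemma is stopworded is caught.  Removed words become
    empty pads; punctuation is retained as tokens.
    """
    if isinstance(gene_text, pd.Series):
        gene_text = gene_text.to_dict()
    if isinstance(groups, pd.Series):
        groups = groups.to_dict()
    lemma_dict = {k.lower(): v.lower() for k, v in (lemma_dict or {}).items()}
    stop = {w.lower() for w in stopwords} | {w.lower() for w in custom_stopwords}
    corpus = TextCorpus()
    for gene in sorted(groups, key=str):
        if gene not in gene_text:
            logger.warning("gene %r has no text record; skipped", gene)
            continue
        tokens = []
        for tok in tokenize(str(gene_text[gene])):
            if _is_punct(tok):
                tokens.append(tok)
                continue
            lemma = lemma_dict.get(tok, tok)
            tokens.append(PAD if lemma in stop else lemma)
        corpus.documents[gene] = tokens
        corpus.groups[gene] = groups[gene]
    return corpus


def unigram_counts(corpus: TextCorpus, by_group: bool = True) -> pd.DataFrame:
    """Word frequencies per group, excluding pads and punctuation."""
    counters: dict[str, Counter] = {}
    for gene, tokens in corpus.documents.items():
        key = corpus.groups[gene] if by_group else "all"
        counters.setdefault(key, Counter()).update(
            t for t in tokens if t != PAD and not _is_punct(t)
        )
    out = pd.DataFrame(counters).fillna(0).astype(int)
    out = out.reindex(sorted(out.index), axis=0)
    return out.reindex(sorted(out.columns), axis=1)


def yates_chi2(a: float, b: float, c: float, d: float) -> float:
    """Chi-square of a 2x2 table with Yates continuity correction.

    The correction subtracts N/2 from |ad - bc| and clamps at zero, so
    near-null tables score exactly 0.
    """
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    num = max(abs(a * d - b * c) - n / 2.0, 0.0)
    return float(n * num**2 / denom)


def keyness(
    counts_target: pd.Series | dict, counts_reference: pd.Series | dict
) -> pd.DataFrame:
    """Signed chi-square keyness of words between two corpora.

    For each word, the 2x2 table is (word vs all other tokens) x
    (target vs reference).  The sign is positive when the word's
    relative frequency is higher in the target corpus.  Rows are sorted
    by signed keyness, descending, so the head reproduces "top keyness
    words" listings.
    """
    t = pd.Series(counts_target, dtype=float)
    r = pd.Series(counts_reference, dtype=float)
    total_t, total_r = float(t.sum()), float(r.sum())
    if total_t <= 0 or total_r <= 0:
        raise ValueError("both corpora must contain countable tokens")
    words = sorted(set(t.index) | set(r.index))
    rows = []
    for w in words:
        a = float(t.get(w, 0.0))
        c = float(r.get(w, 0.0))
        if a == 0 and c == 0:
            continue
        b, d = total_t - a, total_r - c
        chi2 = yates_chi2(a, b, c, d)
        sign = 1.0 if a / total_t >= c / total_r else -1.0
        rows.append(
            {
                "word": w,
                "count_target": int(a),
                "count_reference": int(c),
                "chi2": chi2,
                "keyness": sign * chi2,
                "p": float(sps.chi2.sf(chi2, df=1)),
            }
        )
    out = pd.DataFrame(
        rows, columns=["word", "count_target", "count_reference", "chi2", "keyness", "p"]
    ).set_index("word")
    return out.sort_values(["keyness", "word"], ascending=[False, True], kind="mergesort")


def _bigram_positions(corpus: TextCorpus):
    """All counted adjacency positions: consecutive countable words.

    A pad or punctuation token occupies its position and therefore
    breaks adjacency; bigram slots are words only.
    """
    for gene in sorted(corpus.documents, key=str):
        tokens = corpus.documents[gene]
        for t1, t2 in zip(tokens, tokens[1:]):
            if t1 != PAD and t2 != PAD and not _is_punct(t1) and not _is_punct(t2):
                yield t1, t2


def collocations(corpus: TextCorpus, length: int = 2) -> pd.DataFrame:
    """Bigram collocation log-odds and Wald z over adjacency positions.

    For each observed bigram (w1, w2): n11 = its occurrences, n12 = w1
    followed by another word, n21 = another word followed by w2, n22 =
    the rest, summing to the total number of counted bigram positions.
    lambda = ln(n11*n22 / (n12*n21)) and z = lambda / SE with
    SE = sqrt(sum of reciprocal cells); 0.5 is added to every cell only
    when some cell is zero.
    """
    if length != 2:
        raise NotImplementedError("only bigrams (length 2) are supported")
    pairs = Counter(_bigram_positions(corpus))
    total = sum(pairs.values())
    if total == 0:
        return pd.DataFrame(
            columns=["word1", "word2", "n11", "n12", "n21", "n22", "lambda", "z"]
        )
    first = Counter()
    second = Counter()
    for (w1, w2), c in pairs.items():
        first[w1] += c
        second[w2] += c
    rows = []
    for (w1, w2), n11 in sorted(pairs.items()):
        n12 = first[w1] - n11
        n21 = second[w2] - n11
        n22 = total - n11 - n12 - n21
        cells = np.array([n11, n12, n21, n22], dtype=float)
        if (cells == 0).any():
            cells = cells + 0.5
        lam = float(np.log(cells[0] * cells[3] / (cells[1] * cells[2])))
        se = float(np.sqrt((1.0 / cells).sum()))
        rows.append(
            {
                "word1": w1,
                "word2": w2,
                "n11": n11,
                "n12": n12,
                "n21": n21,
                "n22": n22,
                "lambda": lam,
                "z": lam / se,
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(["z", "word1", "word2"], ascending=[False, True, True],
                           kind="mergesort").reset_index(drop=True)
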