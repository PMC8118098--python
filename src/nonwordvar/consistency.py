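"""Nonword spelling-sound consistency from GPC entropies.

A nonword's *item consistency* is the negated pronunciation entropy of its
most inconsistent syllable: the nonword is syllabified, each syllable is
parsed into graphemes, each grapheme is mapped to the entropy of its
pronunciation distribution in the lexicon, grapheme entropies are averaged
within syllables, the maximum syllable value is taken and multiplied by -1.
Low (strongly negative) values mark nonwords built from graphemes with many
plausible pronunciations; values near 0 mark fully predictable nonwords.

Because the raw metric is nonpositive it has no real logarithm; the model
covariate is ``-ln(H_maxsyll + eps)`` centred over the analysed item set,
which preserves the higher-is-more-consistent orientation (see
``GPCEntropyModel``).  Alternative aggregations (mean/sum over syllables,
single worst grapheme) are computed alongside for the metric-selection step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .lexicon import (
    GPCTable,
    GraphemeRule,
    LexiconEntry,
    build_gpc_table,
    load_default_rules,
    parse_syllable,
)

_VOWELS = set("AEIOU")

# onset clusters legal at an English syllable start (single consonants are
# always legal); used by the rule-based syllabification fallback only —
# a manual overrides table is authoritative when supplied
_LEGAL_ONSETS = {
    "BL", "BR", "CH", "CL", "CR", "DR", "DW", "FL", "FR", "GL", "GR", "GN",
    "KL", "KN", "KR", "PH", "PL", "PR", "PS", "QU", "SC", "SH", "SK", "SL",
    "SM", "SN", "SP", "ST", "SW", "TH", "TR", "TW", "WH", "WR",
    "SCH", "SCR", "SHR", "SPL", "SPR", "SQU", "STR", "THR", "CHR",
}


class ConsistencyError(ValueError):
    """Nonword cannot be scored under the supplied GPC table."""


def _nucleus_mask(word: str) -> list[bool]:
    mask = []
    for i, ch in enumerate(word):
        if ch in _VOWELS:
            mask.append(True)
        elif ch == "Y" and i > 0 and word[i - 1] not in _VOWELS:
            mask.append(True)
        else:
            mask.append(False)
    # final consonant+LE carries a syllabic /l/: its L anchors a nucleus
    if len(word) >= 3 and word.endswith("LE") and word[-3] not in _VOWELS:
        mask[-2] = True
    # a lone final E after a consonant is silent when another nucleus exists
    elif word.endswith("E") and len(word) >= 2 and word[-2] not in _VOWELS | {"E"}:
        if any(mask[:-1]):
            mask[-1] = False
    return mask


def syllabify_nonword(nonword: str, overrides: dict[str, list[str]] | None = None) -> list[str]:
    """Split a nonword into syllables.

    A manual override (map nonword -> syllable list) wins when present.
    Otherwise vowel groups are located (Y is vocalic after a consonant, a
    lone final E after a consonant is silent, final consonant+LE is
    syllabic) and each intervocalic consonant cluster is split so the next
    syllable's onset is the longest legal English onset (onset
    maximisation).  The returned syllables concatenate to the input.
    """
    if not nonword or not nonword.isalpha():
        raise ConsistencyError(f"nonword must be nonempty and alphabetic, got {nonword!r}")
    word = nonword.upper()
    if overrides:
        ov = {k.upper(): v for k, v in overrides.items()}
        if word in ov:
            parts = [p.upper() for p in ov[word]]
            if "".join(parts) != word:
                raise ConsistencyError(
                    f"override for {word!r} does not concatenate to the nonword: {parts}")
            return parts

    mask = _nucleus_mask(word)
    groups: list[tuple[int, int]] = []  # [start, end) of each vowel group
    i = 0
    while i < len(word):
        if mask[i]:
            j = i
            while j < len(word) and mask[j]:
                j += 1
            groups.append((i, j))
            i = j
        else:
            i += 1
    if len(groups) <= 1:
        return [word]

    boundaries = [0]
    for (s1, e1), (s2, e2) in zip(groups, groups[1:]):
        cluster = word[e1:s2]
        onset_len = 0
        for k in range(len(cluster), 0, -1):
            cand = cluster[-k:]
            if k == 1 or cand in _LEGAL_ONSETS:
                onset_len = k
                break
        boundaries.append(s2 - onset_len)
    boundaries.append(len(word))
    return [word[a:b] for a, b in zip(boundaries, boundaries[1:])]


@dataclass
class NonwordParse:
    """A nonword decomposed into syllables and entropy-mapped graphemes."""

    nonword: str
    syllables: list[str]
    graphemes_per_syllable: list[list[tuple[str, float]]]
    provenance: list[list[str]] = field(default_factory=list)  # 'exact' | 'fallback'


@dataclass
class ItemConsistency:
    """Raw consistency (negated max-syllable entropy) and alternatives."""

    nonword: str
    parse: NonwordParse
    raw: float                       # -max over syllables of mean grapheme entropy
    aggregations: dict[str, float]   # alternative (negated) aggregations


def _lookup_entropy(token, table: GPCTable, *, is_first, is_last,
                    word_initial, word_final, following):
    """Entropy for a parsed grapheme: most specific satisfied table rule,
    falling back to unconditioned single-letter rules."""
    cands = [
        r for r in table.entropies
        if r.grapheme == token.grapheme
        and r.matches_position(is_first=is_first, is_last=is_last,
                               word_initial=word_initial, word_final=word_final)
        and r.matches_context(following)
    ]
    if cands:
        rule = max(cands, key=lambda r: r.specificity)
        return [(token.grapheme, table.entropies[rule])], "exact"
    out = []
    for letter in token.grapheme:
        letter_rules = [r for r in table.entropies
                        if r.grapheme == letter and r.position_class == "any"
                        and r.context_set is None]
        if not letter_rules:
            raise ConsistencyError(
                f"no GPC entropy for grapheme {token.grapheme!r} "
                f"(letter {letter!r} has no unconditioned rule in the table)")
        out.append((letter, table.entropies[max(letter_rules, key=lambda r: r.specificity)]))
    return out, "fallback"


def parse_nonword(nonword: str, table: GPCTable,
                  overrides: dict[str, list[str]] | None = None,
                  rules: list[GraphemeRule] | None = None) -> NonwordParse:
    """Syllabify, grapheme-parse and entropy-map a nonword."""
    if rules is None:
        rules = table.rules if table.rules else list(table.entropies)
    syllables = syllabify_nonword(nonword, overrides)
    per_syll: list[list[tuple[str, float]]] = []
    prov: list[list[str]] = []
    for si, syll in enumerate(syllables):
        try:
            tokens = parse_syllable(syll, rules,
                                    word_initial=(si == 0),
                                    word_final=(si == len(syllables) - 1))
        except Exception as err:
            raise ConsistencyError(
                f"cannot parse {nonword!r} (syllable {syll!r}): {err}") from err
        ents: list[tuple[str, float]] = []
        provs: list[str] = []
        for ti, tok in enumerate(tokens):
            following = tokens[ti + 1].grapheme if ti + 1 < len(tokens) else None
            pairs, p = _lookup_entropy(
                tok, table,
                is_first=(ti == 0), is_last=(ti == len(tokens) - 1),
                word_initial=(si == 0 and ti == 0),
                word_final=(si == len(syllables) - 1 and ti == len(tokens) - 1),
                following=following)
            ents.extend(pairs)
            provs.extend([p] * len(pairs))
        per_syll.append(ents)
        prov.append(provs)
    return NonwordParse(nonword.upper(), syllables, per_syll, prov)


def item_consistency(nonword: str, table: GPCTable,
                     overrides: dict[str, list[str]] | None = None,
                     rules: list[GraphemeRule] | None = None) -> ItemConsistency:
    """Score one nonword: raw = -(entropy of its most inconsistent syllable,
    grapheme entropies averaged within syllable); alternative aggregations
    (negated likewise) returned for metric selection."""
    parse = parse_nonword(nonword, table, overrides, rules)
    syll_means = [float(np.mean([h for _, h in ents])) for ents in parse.graphemes_per_syllable]
    all_h = [h for ents in parse.graphemes_per_syllable for _, h in ents]
    raw = -max(syll_means)
    aggregations = {
        "max_syllable_mean": raw,
        "mean_syllable_mean": -float(np.mean(syll_means)),
        "sum_syllable_mean": -float(np.sum(syll_means)),
        "max_grapheme": -float(np.max(all_h)),
        "mean_grapheme": -float(np.mean(all_h)),
        "sum_grapheme": -float(np.sum(all_h)),
    }
    return ItemConsistency(parse.nonword, parse, raw, aggregations)


def select_metric(candidate_metrics: dict[str, np.ndarray], dv: np.ndarray) -> str:
    """Pick the candidate metric with the highest |Pearson r| against the DV.

    Zero-variance candidates are excluded with a warning; ties are broken by
    the candidates' declared (insertion) order.
    """
    dv = np.asarray(dv, dtype=float)
    best_name, best_r = None, -np.inf
    for name, vec in candidate_metrics.items():
        vec = np.asarray(vec, dtype=float)
        if vec.shape != dv.shape:
            raise ValueError(f"metric {name!r} length {vec.shape} != dv {dv.shape}")
        if np.std(vec) == 0:
            warnings.warn(f"metric {name!r} has zero variance; excluded from selection")
            continue
        r = abs(float(np.corrcoef(vec, dv)[0, 1])) if np.std(dv) > 0 else 0.0
        if r > best_r:
            best_name, best_r = name, r
    if best_name is None:
        raise ValueError("no candidate metric with nonzero variance")
    return best_name


class GPCEntropyModel(TransformerMixin, BaseEstimator):
    """Lexicon-fitted nonword consistency scorer.

    ``fit`` derives the GPC table (counts, relative frequencies, per-rule
    entropies) from a syllabified lexicon; ``transform`` maps an iterable of
    nonword strings to a tidy frame of consistency scores.

    Parameters
    ----------
    rules : list[GraphemeRule] or None
        Grapheme inventory; ``None`` loads the bundled English default.
    weighting : {'types', 'tokens'}
        Whether each unique lexicon word counts once or by its frequency.
    eps : float
        Offset inside the covariate log transform ``-ln(H + eps)``.
    transform_variant : {'neg_log', 'raw'}
        Covariate definition: log transform of the max-syllable entropy, or
        the raw negated entropy itself.  Both are centred over the
        transformed item set.
    syllable_overrides : dict[str, list[str]] or None
        Manual syllabifications, authoritative when present.

    Attributes
    ----------
    table_ : GPCTable
        The fitted correspondence table.
    n_rules_ : int
        Number of distinct context-dependent GPC rules observed.
    """

    def __init__(self, rules=None, weighting="types", eps=0.01,
                 transform_variant="neg_log", syllable_overrides=None):
        self.rules = rules
        self.weighting = weighting
        self.eps = eps
        self.transform_variant = transform_variant
        self.syllable_overrides = syllable_overrides

    def _resolve_rules(self):
        return self.rules if self.rules is not None else load_default_rules()

    def fit(self, X, y=None):
        """Fit on a lexicon: a list of LexiconEntry, a GPCTable, or a
        DataFrame with columns word, syl_orth, syl_phon[, freq]."""
        if isinstance(X, GPCTable):
            self.table_ = X
        else:
            if isinstance(X, pd.DataFrame):
                entries = []
                for _, row in X.iterrows():
                    entries.append(LexiconEntry(
                        word=row["word"],
                        syllables_orth=str(row["syl_orth"]).split("-"),
                        syllables_phon=[tuple(s.split(".")) for s in str(row["syl_phon"]).split("-")],
                        frequency=float(row["freq"]) if "freq" in X.columns else 1.0))
                X = entries
            self.table_ = build_gpc_table(list(X), self._resolve_rules(), self.weighting)
        self.n_rules_ = len(self.table_.entropies)
        return self

    def score_item(self, nonword: str) -> ItemConsistency:
        check_is_fitted(self, "table_")
        return item_consistency(nonword, self.table_, self.syllable_overrides,
                                self.table_.rules or None)

    def transform(self, X) -> pd.DataFrame:
        """Score an iterable of nonwords.

        Returns a frame with the raw metric, the centred model covariate and
        every alternative aggregation; centring is over the transformed set.
        """
        check_is_fitted(self, "table_")
        rows = []
        for nw in X:
            ic = self.score_item(nw)
            row = {"nonword": ic.nonword,
                   "syllables": "-".join(ic.parse.syllables),
                   "raw_consistency": ic.raw}
            row.update({f"agg_{k}": v for k, v in ic.aggregations.items()})
            rows.append(row)
        df = pd.DataFrame(rows)
        h_max = -df["raw_consistency"].to_numpy()
        if self.transform_variant == "neg_log":
            cov = -np.log(h_max + self.eps)
        elif self.transform_variant == "raw":
            cov = -h_max
        else:
            raise ValueError(f"unknown transform_variant {self.transform_variant!r}")
        df["covariate"] = cov - cov.mean()
        return df
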