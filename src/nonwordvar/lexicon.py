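"""Context-dependent grapheme-phoneme correspondence (GPC) statistics.

A GPC is a mapping from a grapheme — a letter or letter group functioning as
one spelling unit (EA, CH, C-before-E/I/Y) — to a phoneme, with a relative
frequency estimated from a pronunciation lexicon.  The certainty of a
grapheme's pronunciation is summarised by the Shannon entropy of its
pronunciation distribution, H = sum(-p_i * ln p_i) in nats: H = 0 for a
grapheme that is always pronounced one way, ln k for one pronounced k ways
uniformly.

The lexicon is supplied pre-syllabified (one phoneme code per grapheme is
required within a syllable for the pairing to be unambiguous, so syllables
whose grapheme and phoneme counts disagree are discarded and counted).
Syllables are parsed into graphemes by greedy leftmost-longest match over a
declarative rule inventory; each parsed grapheme is attributed to the most
specific matching rule (context-conditioned beats position-conditioned beats
unconditioned, ties broken by inventory order).
"""

from __future__ import annotations

import importlib.resources
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import entropy as _shannon_entropy

POSITION_CLASSES = ("any", "word_initial", "word_final", "syllable_initial", "syllable_final")


class LexiconError(ValueError):
    """Invalid lexicon entry or rule inventory."""


class SyllableParseError(LexiconError):
    """A syllable could not be segmented into inventory graphemes."""

    def __init__(self, orth: str, position: int):
        self.orth = orth
        self.position = position
        super().__init__(
            f"cannot parse syllable {orth!r}: no inventory grapheme matches at "
            f"position {position} ({orth[position:]!r})"
        )


@dataclass(frozen=True)
class GraphemeRule:
    """One row of the grapheme inventory.

    ``context_set`` restricts the rule to tokens whose *following* grapheme
    (within the same syllable) starts with one of the given letters, e.g.
    C -> /s/ before E, I, Y.  ``order`` is the inventory file position and
    breaks specificity ties deterministically.
    """

    grapheme: str
    position_class: str = "any"
    context_set: frozenset[str] | None = None
    order: int = 0

    def __post_init__(self):
        if not self.grapheme:
            raise LexiconError("rule grapheme must be nonempty")
        if self.position_class not in POSITION_CLASSES:
            raise LexiconError(f"unknown position class {self.position_class!r}")

    @property
    def specificity(self) -> tuple[int, int, int]:
        """Sort key: context-specific > position-specific > unconditioned."""
        return (
            1 if self.context_set is not None else 0,
            1 if self.position_class != "any" else 0,
            -self.order,
        )

    def matches_position(self, *, is_first: bool, is_last: bool,
                         word_initial: bool, word_final: bool) -> bool:
        pc = self.position_class
        if pc == "any":
            return True
        if pc == "word_initial":
            return is_first and word_initial
        if pc == "word_final":
            return is_last and word_final
        if pc == "syllable_initial":
            return is_first
        return is_last  # syllable_final

    def matches_context(self, following: str | None) -> bool:
        if self.context_set is None:
            return True
        return following is not None and following[0] in self.context_set

    def label(self) -> str:
        ctx = "|".join(sorted(self.context_set)) if self.context_set else ""
        return f"{self.grapheme}[{self.position_class}{';' + ctx if ctx else ''}]"


@dataclass(frozen=True)
class ParsedGrapheme:
    """A grapheme token in a parsed syllable with its attributed rule."""

    grapheme: str
    rule: GraphemeRule

    @property
    def position_class(self) -> str:
        return self.rule.position_class

    @property
    def context_set(self) -> frozenset[str] | None:
        return self.rule.context_set


@dataclass
class LexiconEntry:
    """A word with aligned orthographic and phonemic syllabifications.

    ``syllables_phon`` holds, per syllable, the tuple of phoneme codes.
    ``frequency`` is a token weight used when ``weighting='tokens'``.
    """

    word: str
    syllables_orth: list[str]
    syllables_phon: list[tuple[str, ...]]
    frequency: float = 1.0

    def __post_init__(self):
        if len(self.syllables_orth) != len(self.syllables_phon):
            raise LexiconError(
                f"{self.word!r}: {len(self.syllables_orth)} orthographic vs "
                f"{len(self.syllables_phon)} phonemic syllables"
            )
        if not self.syllables_orth:
            raise LexiconError(f"{self.word!r}: no syllables")
        if any(not s for s in self.syllables_orth):
            raise LexiconError(f"{self.word!r}: empty orthographic syllable")
        if any(not p for s in self.syllables_phon for p in s):
            raise LexiconError(f"{self.word!r}: empty phoneme code")
        if self.frequency < 0:
            raise LexiconError(f"{self.word!r}: negative frequency")


@dataclass(frozen=True)
class GPCRecord:
    rule: GraphemeRule
    phoneme: str
    count: float
    relative_frequency: float


@dataclass
class GPCTable:
    """Tallied grapheme-phoneme correspondences with per-rule entropies (nats)."""

    records: list[GPCRecord]
    entropies: dict[GraphemeRule, float]
    n_syllables_used: int
    n_syllables_discarded: int
    rules: list[GraphemeRule] = field(default_factory=list)

    def rules_for(self, grapheme: str) -> list[GraphemeRule]:
        return [r for r in self.entropies if r.grapheme == grapheme]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            rows.append({
                "grapheme": rec.rule.grapheme,
                "position_class": rec.rule.position_class,
                "context_set": "|".join(sorted(rec.rule.context_set)) if rec.rule.context_set else "",
                "phoneme": rec.phoneme,
                "count": rec.count,
                "rel_freq": rec.relative_frequency,
                "entropy": self.entropies[rec.rule],
            })
        return pd.DataFrame(rows, columns=["grapheme", "position_class", "context_set",
                                           "phoneme", "count", "rel_freq", "entropy"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GPCTable":
        df = pd.read_csv(path, keep_default_na=False, dtype={"context_set": str})
        records: list[GPCRecord] = []
        entropies: dict[GraphemeRule, float] = {}
        rule_cache: dict[tuple, GraphemeRule] = {}
        for i, row in df.iterrows():
            key = (row["grapheme"], row["position_class"], row["context_set"])
            if key not in rule_cache:
                ctx = frozenset(row["context_set"].split("|")) if row["context_set"] else None
                rule_cache[key] = GraphemeRule(row["grapheme"], row["position_class"], ctx, order=len(rule_cache))
            rule = rule_cache[key]
            records.append(GPCRecord(rule, str(row["phoneme"]), float(row["count"]),
                                     float(row["rel_freq"])))
            entropies[rule] = float(row["entropy"])
        return cls(records, entropies, n_syllables_used=0, n_syllables_discarded=0,
                   rules=list(rule_cache.values()))


def _viable_rules(rules_by_grapheme, grapheme, *, is_first, is_last,
                  word_initial, word_final, following):
    out = []
    for rule in rules_by_grapheme.get(grapheme, ()):
        if rule.matches_position(is_first=is_first, is_last=is_last,
                                 word_initial=word_initial, word_final=word_final) \
                and rule.matches_context(following):
            out.append(rule)
    return out


def _index_rules(rules: list[GraphemeRule]) -> dict[str, list[GraphemeRule]]:
    by_g: dict[str, list[GraphemeRule]] = {}
    for r in rules:
        by_g.setdefault(r.grapheme, []).append(r)
    return by_g


def parse_syllable(orth: str, rules: list[GraphemeRule], *,
                   word_initial: bool = False,
                   word_final: bool = False) -> list[ParsedGrapheme]:
    """Segment a syllable into graphemes by greedy leftmost-longest match.

    At each position the longest inventory spelling is consumed, provided at
    least one of its rules is satisfied there (position class and
    following-grapheme context).  The token is attributed to the most
    specific satisfied rule.  Raises :class:`SyllableParseError` when no
    spelling matches at some position.
    """
    if not orth:
        raise LexiconError("empty syllable")
    by_g = _index_rules(rules)
    max_len = max(len(g) for g in by_g)

    # Two passes: segmentation needs to know the following grapheme to test
    # context predicates, but the following grapheme depends on segmentation
    # downstream.  Greedy choice makes this well-defined: segment first using
    # position predicates plus a provisional next-letter context, then
    # attribute rules with the realised following grapheme.
    spans: list[str] = []
    pos = 0
    while pos < len(orth):
        chosen = None
        for length in range(min(max_len, len(orth) - pos), 0, -1):
            cand = orth[pos:pos + length]
            if cand not in by_g:
                continue
            is_first = pos == 0
            is_last = pos + length == len(orth)
            following = orth[pos + length:pos + length + 1] or None
            if _viable_rules(by_g, cand, is_first=is_first, is_last=is_last,
                             word_initial=word_initial, word_final=word_final,
                             following=following):
                chosen = cand
                break
        if chosen is None:
            raise SyllableParseError(orth, pos)
        spans.append(chosen)
        pos += len(chosen)

    tokens: list[ParsedGrapheme] = []
    for i, g in enumerate(spans):
        following = spans[i + 1] if i + 1 < len(spans) else None
        cands = _viable_rules(by_g, g, is_first=(i == 0), is_last=(i == len(spans) - 1),
                              word_initial=word_initial, word_final=word_final,
                              following=following)
        if not cands:  # context predicate satisfied by next letter but not next grapheme
            cands = _viable_rules(by_g, g, is_first=(i == 0), is_last=(i == len(spans) - 1),
                                  word_initial=word_initial, word_final=word_final,
                                  following=following[0] if following else None)
        rule = max(cands, key=lambda r: r.specificity)
        tokens.append(ParsedGrapheme(g, rule))
    return tokens


@dataclass(frozen=True)
class AlignedSyllable:
    """A syllable whose graphemes pair 1:1, in order, with its phonemes."""

    orth: str
    graphemes: tuple[ParsedGrapheme, ...]
    phonemes: tuple[str, ...]


def filter_alignable(entry: LexiconEntry, rules: list[GraphemeRule]) -> list[AlignedSyllable]:
    """Return the entry's syllables where grapheme count equals phoneme count.

    Only such syllables allow an unambiguous positional grapheme-phoneme
    pairing; the rest are silently dropped here (``build_gpc_table`` counts
    them).  Unparseable syllables are likewise dropped.
    """
    n_syll = len(entry.syllables_orth)
    kept: list[AlignedSyllable] = []
    for i, (orth, phon) in enumerate(zip(entry.syllables_orth, entry.syllables_phon)):
        try:
            tokens = parse_syllable(orth, rules,
                                    word_initial=(i == 0),
                                    word_final=(i == n_syll - 1))
        except SyllableParseError:
            continue
        if len(tokens) == len(phon):
            kept.append(AlignedSyllable(orth, tuple(tokens), tuple(phon)))
    return kept


def build_gpc_table(lexicon: list[LexiconEntry], rules: list[GraphemeRule],
                    weighting: str = "types") -> GPCTable:
    """Tally GPC counts over all alignable syllables and derive entropies.

    With ``weighting='types'`` each unique (word, pronunciation) entry counts
    once; with ``'tokens'`` entries contribute their ``frequency``.  Relative
    frequencies are normalised within rule; the per-rule entropy is
    H = sum(-p_i ln p_i) over its phoneme distribution, in nats.
    """
    if weighting not in ("types", "tokens"):
        raise LexiconError(f"weighting must be 'types' or 'tokens', got {weighting!r}")
    if not lexicon:
        raise LexiconError("empty lexicon")

    if weighting == "types":
        seen: set[tuple] = set()
        deduped = []
        for e in lexicon:
            key = (e.word, tuple(e.syllables_orth), tuple(e.syllables_phon))
            if key not in seen:
                seen.add(key)
                deduped.append(e)
        lexicon = deduped

    counts: Counter[tuple[GraphemeRule, str]] = Counter()
    n_used = 0
    n_discarded = 0
    for entry in lexicon:
        weight = entry.frequency if weighting == "tokens" else 1.0
        aligned = filter_alignable(entry, rules)
        n_used += len(aligned)
        n_discarded += len(entry.syllables_orth) - len(aligned)
        for syll in aligned:
            for token, phoneme in zip(syll.graphemes, syll.phonemes):
                counts[(token.rule, phoneme)] += weight

    if not counts:
        raise LexiconError("no alignable syllables in lexicon")

    totals: Counter[GraphemeRule] = Counter()
    for (rule, _), c in counts.items():
        totals[rule] += c

    records = [
        GPCRecord(rule, phoneme, c, c / totals[rule])
        for (rule, phoneme), c in sorted(
            counts.items(), key=lambda kv: (kv[0][0].grapheme, kv[0][0].order, kv[0][1])
        )
    ]
    entropies = {}
    for rule in totals:
        ps = np.array([r.relative_frequency for r in records if r.rule == rule])
        entropies[rule] = float(_shannon_entropy(ps))
    return GPCTable(records, entropies, n_syllables_used=n_used,
                    n_syllables_discarded=n_discarded, rules=list(rules))


# ---------------------------------------------------------------------------
# File formats

def read_lexicon_tsv(path) -> list[LexiconEntry]:
    """Read a lexicon TSV: word, syl_orth ('-'-separated syllables),
    syl_phon ('-'-separated syllables of '.'-separated phoneme codes),
    optional freq column."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"word", "syl_orth", "syl_phon"}
    if not required.issubset(df.columns):
        raise LexiconError(f"lexicon file missing columns {required - set(df.columns)}")
    entries = []
    for _, row in df.iterrows():
        freq = float(row["freq"]) if "freq" in df.columns and row["freq"] != "" else 1.0
        entries.append(LexiconEntry(
            word=row["word"],
            syllables_orth=row["syl_orth"].split("-"),
            syllables_phon=[tuple(s.split(".")) for s in row["syl_phon"].split("-")],
            frequency=freq,
        ))
    return entries


def write_lexicon_tsv(entries: list[LexiconEntry], path) -> None:
    rows = [{
        "word": e.word,
        "syl_orth": "-".join(e.syllables_orth),
        "syl_phon": "-".join(".".join(s) for s in e.syllables_phon),
        "freq": e.frequency,
    } for e in entries]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_rules_csv(path) -> list[GraphemeRule]:
    """Read a grapheme inventory CSV: grapheme, position_class, context_set
    (letters '|'-separated, empty for none)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "grapheme" not in df.columns:
        raise LexiconError("rules file needs a 'grapheme' column")
    rules = []
    for i, row in df.iterrows():
        pc = row.get("position_class", "") or "any"
        ctx_raw = row.get("context_set", "")
        ctx = frozenset(ctx_raw.split("|")) if ctx_raw else None
        rules.append(GraphemeRule(row["grapheme"], pc, ctx, order=i))
    return rules


def write_rules_csv(rules: list[GraphemeRule], path) -> None:
    rows = [{
        "grapheme": r.grapheme,
        "position_class": r.position_class,
        "context_set": "|".join(sorted(r.context_set)) if r.context_set else "",
    } for r in rules]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_default_rules() -> list[GraphemeRule]:
    """The bundled English grapheme inventory (single letters as fallback,
    common multi-letter graphemes, and the classic C/G softening contexts)."""
    ref = importlib.resources.files("nonwordvar.data") / "default_graphemes.csv"
    with importlib.resources.as_file(ref) as p:
        return read_rules_csv(p)
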