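"""Statistics over a participant x session x item response table.

The central input is a long-format table of normalised phonemic
transcriptions, one row per (participant, session, item).  From it this
module derives the quantities the downstream models consume:

* distinct-pronunciation counts per participant x item;
* response diversity — Shannon entropy (nats) of the distribution of a
  participant's pronunciations of one item across sessions,
  ``sum(-p_i ln p_i)`` with p_i the proportion of sessions a pronunciation
  was used (0 when identical everywhere, ln(n_sessions) when all distinct);
* novel-pronunciation coding — for sessions >= 2, whether the session's
  response was used by that participant for that item in any earlier session;
* per-session Gower distances between participants' response sets, which for
  purely categorical rows reduce to the proportion of mismatching items
  (computed over mutually non-missing items);
* pronunciation frequencies — how many participants used each pronunciation
  of each item in each session, zero-filled so disused pronunciations show 0.

Pronunciation identity is exact string equality after normalisation (stress
marks stripped, whitespace trimmed, canonical Unicode form).
"""

from __future__ import annotations

import itertools
import unicodedata
import warnings

import numpy as np
import pandas as pd
from scipy.stats import entropy as _shannon_entropy

RESPONSE_COLUMNS = ["participant", "session", "item", "pronunciation"]

#: characters removed by normalisation: IPA primary/secondary stress,
#: vertical lines, and the ASCII/typographic apostrophes often used for stress
_STRESS_MARKS = "ˈˌ’'ǀ‖"


class ResponseTableError(ValueError):
    """The response table violates a structural invariant."""


def normalize_transcription(raw: str) -> str:
    """Canonicalise a phonemic transcription: strip stress marks and
    surrounding whitespace, apply Unicode NFC.  Equality of outputs defines
    'same pronunciation'."""
    if raw is None:
        raise ResponseTableError("empty transcription")
    out = unicodedata.normalize("NFC", str(raw).strip())
    out = "".join(ch for ch in out if ch not in _STRESS_MARKS)
    if not out:
        raise ResponseTableError(f"transcription {raw!r} empty after normalisation")
    return out


def validate_responses(df: pd.DataFrame, normalize: bool = True) -> pd.DataFrame:
    """Check structural invariants and (optionally) normalise transcriptions.

    Requires columns participant/session/item/pronunciation, uniqueness of
    (participant, session, item), and that each participant's sessions form
    a contiguous block 1..s_max (dropping out of later sessions is allowed,
    gaps are not).
    """
    missing = set(RESPONSE_COLUMNS) - set(df.columns)
    if missing:
        raise ResponseTableError(f"response table missing columns {sorted(missing)}")
    df = df.copy()
    df["session"] = df["session"].astype(int)
    if normalize:
        df["pronunciation"] = df["pronunciation"].map(normalize_transcription)
    dup = df.duplicated(subset=["participant", "session", "item"])
    if dup.any():
        first = df.loc[dup, ["participant", "session", "item"]].iloc[0]
        raise ResponseTableError(f"duplicate record for {tuple(first)}")
    for p, sess in df.groupby("participant", observed=True)["session"].unique().items():
        s = np.sort(np.unique(sess))
        if s[0] != 1 or not np.array_equal(s, np.arange(1, len(s) + 1)):
            raise ResponseTableError(
                f"participant {p!r}: sessions {list(s)} are not a contiguous prefix 1..s_max")
    return df


def count_distinct(pronunciations) -> int:
    """Number of different pronunciations across sessions (1..n_sessions)."""
    prons = list(pronunciations)
    if not prons:
        raise ResponseTableError("no sessions for this participant x item")
    return len(set(prons))


def response_diversity(pronunciations) -> float:
    """Entropy (nats) of the pronunciation distribution across sessions."""
    prons = list(pronunciations)
    if not prons:
        raise ResponseTableError("no sessions for this participant x item")
    counts = pd.Series(prons).value_counts().to_numpy()
    return float(_shannon_entropy(counts))


def distinct_counts(df: pd.DataFrame) -> pd.DataFrame:
    """Per participant x item: n_sessions and n_distinct."""
    g = df.groupby(["participant", "item"], observed=True)["pronunciation"]
    out = g.agg(n_sessions="size", n_distinct=lambda s: len(set(s))).reset_index()
    return out


def diversity_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per participant x item: n_sessions, n_distinct and diversity (nats)."""
    out = distinct_counts(df)
    div = (df.groupby(["participant", "item"], observed=True)["pronunciation"]
             .agg(response_diversity).rename("diversity").reset_index())
    return out.merge(div, on=["participant", "item"])


def code_novelty(records: pd.DataFrame) -> list[int]:
    """Novelty flags for one participant x item, sessions 2..s_max.

    Flag is 1 when the session's pronunciation was not used in any earlier
    session by this participant for this item.  Requires contiguous sessions
    starting at 1.
    """
    rec = records.sort_values("session")
    sessions = rec["session"].to_numpy()
    if sessions[0] != 1 or not np.array_equal(sessions, np.arange(1, len(sessions) + 1)):
        raise ResponseTableError(f"sessions {list(sessions)} are not contiguous from 1")
    prons = rec["pronunciation"].tolist()
    flags = []
    seen = {prons[0]}
    for p in prons[1:]:
        flags.append(0 if p in seen else 1)
        seen.add(p)
    return flags


def novelty_table(df: pd.DataFrame) -> pd.DataFrame:
    """Long table participant/item/session/novel for sessions >= 2."""
    rows = []
    for (p, it), grp in df.groupby(["participant", "item"], observed=True):
        flags = code_novelty(grp)
        for s, f in enumerate(flags, start=2):
            rows.append({"participant": p, "item": it, "session": s, "novel": f})
    return pd.DataFrame(rows, columns=["participant", "item", "session", "novel"])


def gower_distances(df: pd.DataFrame) -> pd.DataFrame:
    """All-pairs per-session Gower distances between participants.

    Within each session the response sets form a participants x items
    categorical matrix; the Gower distance between two rows is the
    proportion of mismatching pronunciations over the items both
    participants responded to.  Participants with no responses in a session
    are omitted (with a warning when they appear elsewhere in the table).
    Emits one row per unordered pair: session, participant_a, participant_b,
    distance, n_items_compared.
    """
    rows = []
    all_participants = set(df["participant"])
    for session, grp in df.groupby("session", observed=True):
        mat = grp.pivot(index="participant", columns="item", values="pronunciation")
        absent = all_participants - set(mat.index)
        if absent:
            warnings.warn(f"session {session}: participants {sorted(map(str, absent))} "
                          "have no responses and are excluded")
        participants = list(mat.index)
        values = mat.to_numpy(dtype=object)
        present = mat.notna().to_numpy()
        for ia, ib in itertools.combinations(range(len(participants)), 2):
            both = present[ia] & present[ib]
            n = int(both.sum())
            if n == 0:
                warnings.warn(f"session {session}: no common items for pair "
                              f"({participants[ia]}, {participants[ib]}); skipped")
                continue
            mismatch = np.sum(values[ia, both] != values[ib, both])
            rows.append({"session": session, "participant_a": participants[ia],
                         "participant_b": participants[ib],
                         "distance": mismatch / n, "n_items_compared": n})
    return pd.DataFrame(rows, columns=["session", "participant_a", "participant_b",
                                       "distance", "n_items_compared"])


def pronunciation_frequencies(df: pd.DataFrame, drop_last_session: bool = False) -> pd.DataFrame:
    """Participant counts per (item, pronunciation, session), zero-filled.

    Any pronunciation observed for an item in *some* session gets a row in
    *every* session (frequency 0 where unused), so trajectories across
    sessions are complete.  ``drop_last_session`` removes the final session
    before counting (used when fewer participants completed it).
    """
    if drop_last_session:
        df = df[df["session"] < df["session"].max()]
    sessions = np.sort(df["session"].unique())
    counts = (df.groupby(["item", "pronunciation", "session"], observed=True)
                .size().rename("frequency").reset_index())
    full = (counts[["item", "pronunciation"]].drop_duplicates()
            .merge(pd.DataFrame({"session": sessions}), how="cross"))
    out = full.merge(counts, on=["item", "pronunciation", "session"], how="left")
    out["frequency"] = out["frequency"].fillna(0).astype(int)
    return out.sort_values(["item", "pronunciation", "session"]).reset_index(drop=True)


def read_responses_csv(path, normalize: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant": str, "item": str, "pronunciation": str})
    return validate_responses(df, normalize=normalize)


def write_responses_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
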