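"""Synthetic reader populations for end-to-end testing of the pipeline.

No raw multi-session nonword-reading corpus is freely redistributable, and
the grapheme-phoneme statistics of English require a licensed lexical
database.  This module therefore generates (a) syllabified phonemic
lexicons with *known* grapheme-pronunciation distributions, so the GPC /
consistency stages can be validated against ground truth, and (b)
multi-session response tables with the generative structure the analyses
presuppose:

* each grapheme has a population pronunciation distribution (its entropy is
  the item-consistency ground truth);
* each participant's knowledge of an item's pronunciation distribution is a
  Dirichlet perturbation of the population distribution with concentration
  ``kappa`` (large kappa = faithful knowledge), optionally coupled to a
  participant literacy draw;
* across sessions responses follow a knowledge-weighted Polya-urn
  repetition dynamic: at session t each past response token carries urn
  weight ``alpha(t)`` times the participant's knowledge probability of
  that response, against a unit weight on a fresh draw from knowledge.
  Reinforcement therefore favours past responses the participant also
  believes in: idiosyncratic first-session draws are pruned rather than
  locked in.  A nondecreasing alpha produces the settling phenomena the
  analyses measure (declining novelty, shrinking inter-participant
  distances, frequent pronunciations spreading while rare ones drop out).

Defaults mirror the repeated-session reading-aloud design the pipeline
targets: 22 participants x 50 disyllabic nonwords x 5 sessions, with two
participants missing the final session.

The module also provides *parametric* generators that simulate directly
from each analysis stage's model equation with known coefficients; these
are what the recovery suite uses for type-I error and CI-coverage
calibration, since the urn mechanism has no true null for some effects
(novelty mechanically declines whenever the response support is finite).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lexicon import GraphemeRule, LexiconEntry

# ---------------------------------------------------------------------------
# Generating grapheme inventory

#: population pronunciation distributions per grapheme: graded ambiguity,
#: from fully deterministic consonants to a three-way vowel
DEFAULT_INVENTORY: dict[str, dict[str, float]] = {
    # onsets / codas
    "B": {"b": 1.0}, "D": {"d": 1.0}, "F": {"f": 1.0}, "K": {"k": 1.0},
    "L": {"l": 1.0}, "M": {"m": 1.0}, "N": {"n": 1.0}, "P": {"p": 1.0},
    "R": {"r": 1.0}, "S": {"s": 1.0}, "T": {"t": 1.0},
    "G": {"g": 0.7, "dZ": 0.3},
    "C": {"k": 0.75, "s": 0.25},
    "CH": {"tS": 0.7, "k": 0.3},
    "TH": {"T": 0.65, "D": 0.35},
    # nuclei
    "A": {"{": 0.5, "eI": 0.5},
    "E": {"E": 0.7, "i": 0.3},
    "I": {"I": 0.85, "aI": 0.15},
    "O": {"Q": 0.6, "@U": 0.3, "u": 0.1},
    "U": {"V": 1.0},
    "EE": {"i": 0.9, "E": 0.1},
    "OO": {"u": 0.5, "U": 0.5},
}

_NUCLEI = ("A", "E", "I", "O", "U", "EE", "OO")
_ONSETS = ("B", "D", "F", "G", "K", "L", "M", "N", "P", "R", "S", "T", "C", "CH", "TH")
_CODAS = ("B", "D", "F", "G", "K", "L", "M", "N", "P", "S", "T", "CH", "TH")


def _entropy(probs) -> float:
    p = np.asarray(list(probs), dtype=float)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


@dataclass
class SimConfig:
    """Parameters of the synthetic reader population and session dynamic.

    ``repeat_strength`` is alpha(t) for sessions 1..n_sessions: the urn
    weight of each past response token relative to a unit weight on a fresh
    draw from knowledge; alpha(1) is ignored (there is no past).  A
    nondecreasing schedule yields settling across sessions.
    ``knowledge_noise`` is the Dirichlet concentration kappa scaling the
    population distribution (larger = participants closer to it).
    ``literacy_effect`` couples a standard-normal literacy draw to kappa
    multiplicatively (0 = no coupling).  ``decouple_consistency`` reassigns
    generating pronunciation distributions across items at random, severing
    the item-consistency / behaviour link while keeping the measured
    covariate intact (a true null for the consistency effect).
    """

    n_participants: int = 22
    n_items: int = 50
    n_sessions: int = 5
    dropout: int = 2
    inventory: dict[str, dict[str, float]] = field(default_factory=lambda: dict(DEFAULT_INVENTORY))
    knowledge_noise: float = 8.0
    repeat_strength: tuple[float, ...] = (0.0, 4.0, 6.0, 8.0, 10.0)
    literacy_effect: float = 0.0
    decouple_consistency: bool = False
    seed: int = 0

    def __post_init__(self):
        for g, dist in self.inventory.items():
            tot = sum(dist.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"grapheme {g!r}: probabilities sum to {tot}")
        if len(self.repeat_strength) < self.n_sessions:
            raise ValueError("repeat_strength must cover every session")
        if self.dropout >= self.n_participants:
            raise ValueError("dropout must leave at least one participant")


@dataclass
class SimTruth:
    """Ground truth for scoring parameter recovery."""

    items: pd.DataFrame          # item, syllables, true_entropy, true_consistency
    participants: pd.DataFrame   # participant, literacy_latent, kappa
    config: SimConfig
    expected_signs: dict[str, int] = field(default_factory=lambda: {
        "diversity_consistency": -1,   # more consistent -> less diverse
        "novelty_session": -1,         # later sessions -> fewer novel responses
        "novelty_consistency": -1,
        "distance_session": -1,        # participants converge over sessions
        "trajectory_intercept_slope_r": +1,
    })


# ---------------------------------------------------------------------------
# Lexicon generation

def make_lexicon(inventory: dict[str, dict[str, float]] | None = None,
                 n_words: int = 800,
                 seed: int | np.random.Generator = 0
                 ) -> tuple[list[LexiconEntry], list[GraphemeRule]]:
    """Sample a syllabified phonemic lexicon from the generating inventory.

    Words have one or two CVC syllables; each grapheme's phoneme is drawn
    from its population distribution, so empirical GPC relative frequencies
    converge to the inventory as ``n_words`` grows (tally with
    ``weighting='tokens'`` to keep repeated spellings).  Returns the
    entries plus a flat unconditioned rule inventory covering them.
    """
    inventory = dict(DEFAULT_INVENTORY) if inventory is None else inventory
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    graphemes = sorted(inventory, key=len, reverse=True)
    rules = [GraphemeRule(g, "any", None, order=i) for i, g in enumerate(graphemes)]
    onsets = [g for g in _ONSETS if g in inventory]
    nuclei = [g for g in _NUCLEI if g in inventory]
    codas = [g for g in _CODAS if g in inventory]

    entries = []
    for _ in range(n_words):
        n_syll = 1 + rng.integers(0, 2)
        orth_sylls, phon_sylls = [], []
        for _ in range(n_syll):
            gs = [rng.choice(onsets), rng.choice(nuclei), rng.choice(codas)]
            phon = []
            for g in gs:
                phonemes = list(inventory[g])
                probs = np.array(list(inventory[g].values()))
                phon.append(str(rng.choice(phonemes, p=probs)))
            orth_sylls.append("".join(gs))
            phon_sylls.append(tuple(phon))
        entries.append(LexiconEntry("".join(orth_sylls), orth_sylls, phon_sylls))
    return entries, rules


def make_nonwords(inventory: dict[str, dict[str, float]],
                  n_items: int, rng: np.random.Generator
                  ) -> tuple[list[str], dict[str, list[str]], pd.DataFrame, list[dict]]:
    """Sample distinct disyllabic CVC-CVC nonwords.

    Returns the item strings, their (known) syllabification overrides, a
    ground-truth frame with each item's max-syllable mean entropy, and the
    per-item grapheme lists used downstream for response generation.
    """
    onsets = [g for g in _ONSETS if g in inventory]
    nuclei = [g for g in _NUCLEI if g in inventory]
    codas = [g for g in _CODAS if g in inventory]
    items, overrides, meta = [], {}, []
    seen = set()
    truth_rows = []
    attempts = 0
    while len(items) < n_items:
        attempts += 1
        if attempts > 100 * n_items:
            raise RuntimeError("could not sample enough distinct nonwords")
        sylls = []
        for _ in range(2):
            sylls.append([str(rng.choice(onsets)), str(rng.choice(nuclei)), str(rng.choice(codas))])
        word = "".join(g for s in sylls for g in s)
        if word in seen:
            continue
        seen.add(word)
        syll_strs = ["".join(s) for s in sylls]
        syll_entropies = [float(np.mean([_entropy(inventory[g].values()) for g in s]))
                          for s in sylls]
        h_max = max(syll_entropies)
        items.append(word)
        overrides[word] = syll_strs
        meta.append({"item": word, "graphemes": [g for s in sylls for g in s]})
        truth_rows.append({"item": word, "syllables": "-".join(syll_strs),
                           "true_entropy": h_max, "true_consistency": -h_max})
    return items, overrides, pd.DataFrame(truth_rows), meta


# ---------------------------------------------------------------------------
# Response simulation (Dirichlet knowledge + Polya-urn repetition)

def _item_pronunciation_space(graphemes, inventory):
    """Joint pronunciation distribution of an item: the product over its
    graphemes of their phoneme distributions."""
    choices = [list(inventory[g].items()) for g in graphemes]
    prons, probs = [], []
    for combo in itertools.product(*choices):
        prons.append("".join(ph for ph, _ in combo))
        probs.append(float(np.prod([pr for _, pr in combo])))
    return np.array(prons), np.array(probs)


def simulate_responses(config: SimConfig | None = None
                       ) -> tuple[pd.DataFrame, SimTruth]:
    """Generate a participant x session x item response table.

    Deterministic given ``config.seed``.  Also returns the ground truth
    (item entropies, participant literacy/kappa draws, expected effect
    signs) sufficient to score parameter recovery.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    inventory = cfg.inventory

    items, overrides, item_truth, meta = make_nonwords(inventory, cfg.n_items, rng)
    spaces = {m["item"]: _item_pronunciation_space(m["graphemes"], inventory) for m in meta}
    gen_items = list(items)
    if cfg.decouple_consistency:
        gen_items = [items[i] for i in rng.permutation(cfg.n_items)]
    gen_space = {item: spaces[gen] for item, gen in zip(items, gen_items)}

    participants = [f"P{j + 1:02d}" for j in range(cfg.n_participants)]
    literacy_latent = rng.standard_normal(cfg.n_participants)
    kappas = cfg.knowledge_noise * np.exp(cfg.literacy_effect * literacy_latent)

    rows = []
    for j, part in enumerate(participants):
        n_sess = cfg.n_sessions - (1 if j >= cfg.n_participants - cfg.dropout else 0)
        for item in items:
            prons, pop = gen_space[item]
            alpha_dir = np.maximum(kappas[j] * pop, 1e-6)
            knowledge = rng.dirichlet(alpha_dir)
            if knowledge.sum() <= 0 or not np.isfinite(knowledge).all():
                knowledge = pop
            knowledge = knowledge / knowledge.sum()
            know_of = dict(zip(prons, knowledge))
            past: list[str] = []
            for t in range(1, n_sess + 1):
                a_t = cfg.repeat_strength[t - 1]
                # urn weight per past token: alpha(t) x knowledge probability,
                # so reinforcement prunes low-credence responses
                weights = {}
                for r in past:
                    weights[r] = weights.get(r, 0.0) + a_t * know_of[r]
                w_past = sum(weights.values())
                if past and rng.random() < w_past / (w_past + 1.0):
                    opts = list(weights)
                    w = np.array([weights[r] for r in opts])
                    resp = str(opts[rng.choice(len(opts), p=w / w.sum())])
                else:
                    resp = str(prons[rng.choice(len(prons), p=knowledge)])
                past.append(resp)
                rows.append({"participant": part, "session": t,
                             "item": item, "pronunciation": resp})

    responses = pd.DataFrame(rows, columns=["participant", "session", "item", "pronunciation"])
    truth = SimTruth(
        items=item_truth,
        participants=pd.DataFrame({"participant": participants,
                                   "literacy_latent": literacy_latent,
                                   "kappa": kappas}),
        config=cfg,
    )
    return responses, truth


def simulate_literacy_scores(truth: SimTruth, rng: np.random.Generator,
                             reliability: float = 0.8) -> pd.DataFrame:
    """Spelling and vocabulary raw scores loading on the latent literacy
    draw with the given reliability (plus independent noise)."""
    lat = truth.participants["literacy_latent"].to_numpy()
    noise = np.sqrt(1.0 - reliability**2)
    spelling = 25 + 5 * (reliability * lat + noise * rng.standard_normal(len(lat)))
    vocab = 28 + 4 * (reliability * lat + noise * rng.standard_normal(len(lat)))
    return pd.DataFrame({"participant": truth.participants["participant"],
                         "spelling": np.round(spelling, 1),
                         "vocabulary": np.round(vocab, 1)})


def syllable_overrides(truth: SimTruth) -> dict[str, list[str]]:
    """The generator's known syllabifications, as a consistency override map."""
    return {row["item"]: row["syllables"].split("-") for _, row in truth.items.iterrows()}


# ---------------------------------------------------------------------------
# Parametric generators (simulate directly from each stage's model equation)

def parametric_diversity(n_participants=22, n_items=50, b_consistency=-0.3,
                         b_literacy=0.0, b_interaction=0.0, sd_item=0.15,
                         sd_participant=0.2, sd_slope=0.05, sd_resid=0.3,
                         seed=0) -> pd.DataFrame:
    """Diversity table drawn from the Analysis-2 LMM with known coefficients."""
    rng = np.random.default_rng(seed)
    cons = rng.standard_normal(n_items)
    lit = rng.standard_normal(n_participants)
    u_item = sd_item * rng.standard_normal(n_items)
    u_part = sd_participant * rng.standard_normal(n_participants)
    u_slope = sd_slope * rng.standard_normal(n_participants)
    rows = []
    for j in range(n_participants):
        for i in range(n_items):
            mu = (0.5 + b_consistency * cons[i] + b_literacy * lit[j]
                  + b_interaction * cons[i] * lit[j]
                  + u_item[i] + u_part[j] + u_slope[j] * cons[i])
            rows.append({"participant": f"P{j:02d}", "item": f"I{i:02d}",
                         "consistency": cons[i], "literacy": lit[j],
                         "diversity": mu + sd_resid * rng.standard_normal()})
    return pd.DataFrame(rows)


def parametric_novelty(n_participants=22, n_items=50, n_sessions=5,
                       b_session=-0.8, b_consistency=-0.2, b_literacy=0.0,
                       sd_participant=0.4, sd_item=0.4, b0=-0.5,
                       seed=0) -> pd.DataFrame:
    """Novelty table drawn from the Analysis-3 GLMM with known coefficients."""
    rng = np.random.default_rng(seed)
    cons = rng.standard_normal(n_items)
    lit = rng.standard_normal(n_participants)
    u_part = sd_participant * rng.standard_normal(n_participants)
    u_item = sd_item * rng.standard_normal(n_items)
    sessions = np.arange(2, n_sessions + 1)
    s_c = sessions - sessions.mean()
    rows = []
    for j in range(n_participants):
        for i in range(n_items):
            for s, sc in zip(sessions, s_c):
                eta = (b0 + b_session * sc + b_consistency * cons[i]
                       + b_literacy * lit[j] + u_part[j] + u_item[i])
                rows.append({"participant": f"P{j:02d}", "item": f"I{i:02d}",
                             "session": s, "consistency": cons[i],
                             "literacy": lit[j],
                             "novel": int(rng.random() < 1 / (1 + np.exp(-eta)))})
    return pd.DataFrame(rows)


def parametric_distance(n_participants=22, n_sessions=5, dropout=2,
                        b_session=-0.02, b0=0.6, sd_int=0.05, sd_slope=0.01,
                        sd_resid=0.04, seed=0) -> pd.DataFrame:
    """Distance-pair table drawn from the Analysis-4 LMM with known
    coefficients, on the paper-sized pair grid (1,114 pairs by default)."""
    rng = np.random.default_rng(seed)
    parts = [f"P{j:02d}" for j in range(n_participants)]
    u_int = sd_int * rng.standard_normal(n_participants)
    u_slo = sd_slope * rng.standard_normal(n_participants)
    sess = np.arange(1, n_sessions + 1)
    s_z = (sess - sess.mean()) / sess.std(ddof=1)
    rows = []
    for s, sz in zip(sess, s_z):
        present = n_participants - (dropout if s == n_sessions else 0)
        for a in range(present):
            for b in range(a + 1, present):
                mu = (b0 + b_session * sz + u_int[a] + u_slo[a] * sz
                      + u_int[b] + u_slo[b] * sz)
                rows.append({"session": s, "participant_a": parts[a],
                             "participant_b": parts[b],
                             "distance": mu + sd_resid * rng.standard_normal()})
    return pd.DataFrame(rows)


def recovery_suite(n_replicates: int = 25, seed: int = 0,
                   effect: str = "strong",
                   stages: tuple[str, ...] = ("diversity", "novelty", "distance", "trajectory"),
                   mode: str = "parametric",
                   sim_config: SimConfig | None = None) -> pd.DataFrame:
    """Parameter-recovery / calibration study over the four model stages.

    ``mode='parametric'`` simulates each stage directly from its model
    equation at the repeated-session design size (22 x 50 x 5) with known
    coefficients — ``effect='strong'`` scores sign recovery, bias, RMSE and
    95% CI coverage of the generating coefficient; ``effect='null'`` sets
    the generating coefficients to zero and records the p values of every
    null term (type-I calibration).  ``mode='mechanistic'`` instead runs
    the full urn-model pipeline per replicate (lexicon -> GPC -> consistency
    -> statistics -> fits) and scores recovery of the expected effect signs;
    it has no true coefficients, so bias/coverage are not defined there.

    Returns one row per (stage, term) with the aggregated metrics; per-
    replicate failures are counted, never fatal.
    """
    from .analyses import (composite_literacy, fit_distance_lmm, fit_diversity_lmm,
                           fit_novelty_glmm, fit_trajectories)

    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    records: list[dict] = []

    if mode == "mechanistic":
        cfg0 = sim_config or SimConfig()
        for rs in rep_seeds:
            try:
                signs = _mechanistic_replicate(dataclasses_replace(cfg0, seed=int(rs)))
            except Exception as err:  # recorded, not fatal
                records.append({"stage": "pipeline", "term": "error", "seed": int(rs),
                                "failed": True, "message": str(err)})
                continue
            for (stage, term), sign_ok in signs.items():
                records.append({"stage": stage, "term": term, "seed": int(rs),
                                "failed": False, "sign_ok": sign_ok})
        df = pd.DataFrame(records)
        ok = df[~df["failed"]]
        out = (ok.groupby(["stage", "term"])["sign_ok"].agg(["mean", "size"])
                 .rename(columns={"mean": "sign_rate", "size": "n_ok"}).reset_index())
        out["n_failed"] = int(df["failed"].sum())
        return out

    strong = effect == "strong"
    plans = {
        "diversity": {
            "gen": lambda s: parametric_diversity(
                b_consistency=-0.3 if strong else 0.0, b_literacy=0.0, seed=s),
            "fit": fit_diversity_lmm,
            "targets": {"consistency": -0.3 if strong else 0.0},
            "null_terms": ("consistency", "literacy"),
        },
        "novelty": {
            "gen": lambda s: parametric_novelty(
                b_session=-0.8 if strong else 0.0,
                b_consistency=-0.2 if strong else 0.0, b_literacy=0.0, seed=s),
            "fit": fit_novelty_glmm,
            "targets": {"session_c": -0.8 if strong else 0.0,
                        "consistency": -0.2 if strong else 0.0},
            "null_terms": ("session_c", "consistency", "literacy"),
        },
        "distance": {
            "gen": lambda s: parametric_distance(
                b_session=-0.02 if strong else 0.0, seed=s),
            "fit": fit_distance_lmm,
            "targets": {"session_z": -0.02 if strong else 0.0},
            "null_terms": ("session_z",),
        },
        "trajectory": {
            "gen": lambda s: parametric_trajectories(
                rho=0.5 if strong else 0.0, sd_slope=0.3, sd_resid=0.3, seed=s),
            "fit": fit_trajectories,
            "targets": {"intercept_slope_r": 0.5 if strong else 0.0},
            "null_terms": (),
        },
    }

    from scipy.stats import t as _t

    for stage in stages:
        plan = plans[stage]
        for rs in rep_seeds:
            try:
                data = plan["gen"](int(rs))
                fitted = plan["fit"](data)
            except Exception as err:
                records.append({"stage": stage, "term": "error", "seed": int(rs),
                                "failed": True, "message": str(err)})
                continue
            if stage == "trajectory":
                true = plan["targets"]["intercept_slope_r"]
                records.append({"stage": stage, "term": "intercept_slope_r",
                                "seed": int(rs), "failed": False,
                                "estimate": fitted.r, "true": true,
                                "sign_ok": (np.sign(fitted.r) == np.sign(true))
                                if true != 0 else np.nan,
                                "covered": np.nan, "p": np.nan})
                continue
            fe = fitted.fixed_effects
            terms = plan["targets"] if strong else {t: 0.0 for t in plan["null_terms"]}
            for term, true in terms.items():
                est = float(fe.loc[term, "estimate"])
                se = float(fe.loc[term, "se"])
                dfree = float(fe.loc[term, "df"])
                crit = 1.959964 if not np.isfinite(dfree) else float(_t.ppf(0.975, dfree))
                records.append({"stage": stage, "term": term, "seed": int(rs),
                                "failed": False, "estimate": est, "true": true,
                                "sign_ok": (np.sign(est) == np.sign(true))
                                if true != 0 else np.nan,
                                "covered": abs(est - true) <= crit * se,
                                "p": float(fe.loc[term, "p"])})

    df = pd.DataFrame(records)
    ok = df[~df["failed"]].copy()
    rows = []
    for (stage, term), grp in ok.groupby(["stage", "term"]):
        true = grp["true"].iloc[0]
        rows.append({
            "stage": stage, "term": term, "true": true,
            "n_ok": len(grp), "n_failed": int((df["failed"] & (df["stage"] == stage)).sum()),
            "sign_rate": grp["sign_ok"].mean() if grp["sign_ok"].notna().any() else np.nan,
            "bias": (grp["estimate"] - grp["true"]).mean(),
            "rmse": float(np.sqrt(((grp["estimate"] - grp["true"]) ** 2).mean())),
            "coverage": grp["covered"].mean() if grp["covered"].notna().any() else np.nan,
            "type1": (grp["p"] < 0.05).mean() if (not strong and grp["p"].notna().any()) else np.nan,
        })
    return pd.DataFrame(rows)


def dataclasses_replace(cfg: SimConfig, **kw) -> SimConfig:
    import dataclasses
    return dataclasses.replace(cfg, **kw)


def _mechanistic_replicate(cfg: SimConfig) -> dict[tuple[str, str], bool]:
    """One full-pipeline replicate; returns per-(stage, term) sign success."""
    from .analyses import (composite_literacy, fit_distance_lmm, fit_diversity_lmm,
                           fit_novelty_glmm, fit_trajectories)
    from .consistency import GPCEntropyModel
    from .responses import (diversity_table, gower_distances, novelty_table,
                            pronunciation_frequencies)

    rng = np.random.default_rng(cfg.seed + 977)
    responses, truth = simulate_responses(cfg)
    entries, rules = make_lexicon(cfg.inventory, n_words=600, seed=rng)
    model = GPCEntropyModel(rules=rules, weighting="tokens",
                            syllable_overrides=syllable_overrides(truth)).fit(entries)
    scores = model.transform(truth.items["item"])
    lit = composite_literacy(simulate_literacy_scores(truth, rng))

    div = diversity_table(responses)
    nov = novelty_table(responses)
    dist = gower_distances(responses)
    freq = pronunciation_frequencies(responses, drop_last_session=True)

    cov = scores[["nonword", "covariate"]].rename(
        columns={"nonword": "item", "covariate": "consistency"})

    def joined(base):
        return base.merge(cov, on="item").merge(lit[["participant", "literacy"]],
                                                on="participant")

    out: dict[tuple[str, str], bool] = {}
    r2 = fit_diversity_lmm(joined(div))
    out[("diversity", "consistency")] = r2.fixed_effects.loc["consistency", "estimate"] < 0
    r3 = fit_novelty_glmm(joined(nov))
    out[("novelty", "session_c")] = r3.fixed_effects.loc["session_c", "estimate"] < 0
    out[("novelty", "consistency")] = r3.fixed_effects.loc["consistency", "estimate"] < 0
    r4 = fit_distance_lmm(dist)
    out[("distance", "session_z")] = r4.fixed_effects.loc["session_z", "estimate"] < 0
    traj = fit_trajectories(freq)
    out[("trajectory", "intercept_slope_r")] = traj.r > 0
    return out


def parametric_trajectories(n_prons=300, n_sessions=4, rho=0.5,
                            sd_int=1.0, sd_slope=0.08, sd_resid=0.5,
                            seed=0) -> pd.DataFrame:
    """Frequency table drawn from the Analysis-5 LMM: per-pronunciation
    intercepts and slopes correlated at ``rho``."""
    rng = np.random.default_rng(seed)
    cov = np.array([[sd_int**2, rho * sd_int * sd_slope],
                    [rho * sd_int * sd_slope, sd_slope**2]])
    eff = rng.multivariate_normal([0.0, 0.0], cov, size=n_prons)
    rows = []
    for g in range(n_prons):
        for s in range(1, n_sessions + 1):
            mu = eff[g, 0] + eff[g, 1] * s
            rows.append({"item": f"I{g // 8:02d}", "pronunciation": f"pr{g:03d}",
                         "session": s,
                         "frequency": mu + sd_resid * rng.standard_normal()})
    return pd.DataFrame(rows)
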