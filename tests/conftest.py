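import pytest
from hypothesis import settings

from nonwordvar.lexicon import GPCRecord, GPCTable, GraphemeRule

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def make_entropy_table(entropies: dict[str, float],
                       position: str = "any") -> GPCTable:
    """A GPCTable with one unconditioned rule per grapheme and the given
    entropy, for tests that exercise scoring without a lexicon."""
    rules = [GraphemeRule(g, position, None, order=i)
             for i, g in enumerate(entropies)]
    ent = {r: entropies[r.grapheme] for r in rules}
    records = [GPCRecord(r, "x", 1.0, 1.0) for r in rules]
    return GPCTable(records, ent, n_syllables_used=0, n_syllables_discarded=0,
                    rules=rules)


@pytest.fixture(scope="session")
def default_sim():
    """One default-configuration simulated dataset, shared across tests."""
    from nonwordvar.simulate import SimConfig, simulate_responses

    responses, truth = simulate_responses(SimConfig(seed=20210513 % 9973))
    return responses, truth


@pytest.fixture(scope="session")
def golden_lme4():
    import json
    from pathlib import Path

    return json.loads((Path(__file__).parent / "data" / "golden_lme4.json").read_text())


@pytest.fixture()
def single_letter_rules():
    return [GraphemeRule(ch, "any", None, order=i)
            for i, ch in enumerate("ABCDEFGHIJKLMNOPQRSTUVWXYZ")]
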