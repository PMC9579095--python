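import pytest

from edlsim import (
    FrequencyTable,
    dog_rabbit_paradigm,
    light_tone_paradigm,
    negative_patterning_paradigm,
    outcome_competition_paradigm,
)


def blocking_table() -> FrequencyTable:
    """The blocking design as a frequency table (light twice as frequent as tone)."""
    return FrequencyTable.from_rows(
        [
            ({"light"}, {"food"}, 1),
            ({"light", "tone"}, {"food"}, 1),
        ]
    )


@pytest.fixture(scope="session")
def fixture_designs() -> dict[str, FrequencyTable]:
    """All built-in training designs, keyed by name."""
    return {
        "outcome_competition": outcome_competition_paradigm(),
        "blocking": blocking_table(),
        "light_tone_independent": light_tone_paradigm("independent"),
        "light_tone_interacting": light_tone_paradigm("interacting"),
        "dog_rabbit_1": dog_rabbit_paradigm(1),
        "dog_rabbit_2": dog_rabbit_paradigm(2),
        "negative_patterning_elemental": negative_patterning_paradigm("elemental"),
        "negative_patterning_configural": negative_patterning_paradigm("configural"),
        "negative_patterning_mixed": negative_patterning_paradigm("mixed"),
    }
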