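"""Shared fixtures: the bundled lexicon, compiled rules, worked examples."""

import pytest

from dsnorm import RuleConfig, compile_rules, load_demo_lexicon

#: Product names whose structure is known, with the expected template.
WORKED_EXAMPLES = [
    ("Herb Pharm Elderberry", "BN IN"),
    ("Bronson Laboratories Vitamin E 200 IU", "BN IN STR"),
    ("NutraBio Melatonin", "BN IN"),
    ("TERRAVITA Potassium Citrate Powder", "BN IN DF"),
    ("Optimum Nutrition Tribulus 625 MG Caps", "BN IN STR DF"),
    ("Nature's Answer Hawthorn Berry", "BN IN PLNT"),
]

#: The five template exemplars (every worked example except the first).
TEMPLATE_EXEMPLARS = WORKED_EXAMPLES[1:]


@pytest.fixture(scope="session")
def demo_lexicon():
    return load_demo_lexicon()


@pytest.fixture(scope="session")
def default_rules(demo_lexicon):
    return compile_rules(demo_lexicon)


@pytest.fixture(scope="session")
def no_heuristic_rules(demo_lexicon):
    return compile_rules(demo_lexicon, RuleConfig(brand_heuristic=False))
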