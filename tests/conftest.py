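"""Shared fixtures and an evaluation oracle independent of the AST code."""

from itertools import product

import pytest
from hypothesis import settings

from gas5net import canonical_fixtures, load_gas5_model, run_full_suite

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def gas5_model():
    return load_gas5_model()


@pytest.fixture(scope="session")
def suite_result(gas5_model):
    """The full WT + 14-perturbation suite, computed once."""
    return run_full_suite(gas5_model)


@pytest.fixture(scope="session")
def fixtures():
    return canonical_fixtures()


def oracle_eval(rule_text: str, state) -> int:
    """Evaluate serialized rule text through Python's own parser.

    Translates the dialect to a Python boolean expression and lets
    ``eval`` do the work — a route that shares no code with the package's
    AST evaluator, so it can arbitrate truth tables.
    """
    py = rule_text.replace("!", " not ").replace("&", " and ").replace("|", " or ")
    env = {k: bool(v) for k, v in state.items()}
    return int(eval(py, {"__builtins__": {}}, env))


def oracle_truth_table(rule_text: str, variables):
    """Full truth table of serialized rule text via :func:`oracle_eval`."""
    variables = sorted(variables)
    return {
        bits: oracle_eval(rule_text, dict(zip(variables, bits)))
        for bits in product((0, 1), repeat=len(variables))
    }
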