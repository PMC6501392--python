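"""Access to the packaged example configurations."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

FIXTURES = {
    "smarthealth_scorecard": "smarthealth_scorecard.yaml",
    "pacific_salt_scorecard": "pacific_salt_scorecard.yaml",
    "smarthealth_config": "smarthealth_config.yaml",
    "pacific_salt_config": "pacific_salt_config.yaml",
}


def fixture_path(name: str) -> Path:
    """Path to a packaged example config by short name (see ``FIXTURES``)."""
    try:
        filename = FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(FIXTURES)}") from None
    return Path(resources.files("faitkit.data") / filename)
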