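"""Loaders for the packaged exercise catalog and corrective rule table."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml

from .kinematics import ExerciseConfig


class UnknownExerciseError(KeyError):
    pass


def _load_yaml(filename: str) -> dict:
    ref = resources.files("poseform.data").joinpath(filename)
    with ref.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


@lru_cache(maxsize=1)
def _catalog() -> dict[str, ExerciseConfig]:
    raw = _load_yaml("exercises.yaml")["exercises"]
    return {
        name: ExerciseConfig(name=name, **entry) for name, entry in raw.items()
    }


def list_exercises() -> list[str]:
    return sorted(_catalog())


def load_exercise(name: str) -> ExerciseConfig:
    """The packaged preset for one of the seven catalog exercises."""
    key = name.strip().lower().replace("-", "_").replace(" ", "_")
    try:
        return _catalog()[key]
    except KeyError:
        raise UnknownExerciseError(
            f"unknown exercise {name!r}; catalog: {', '.join(list_exercises())}"
        ) from None


@lru_cache(maxsize=1)
def corrective_rules() -> dict:
    """Deficiency-code -> level -> recommendation mapping."""
    return _load_yaml("corrective_exercises.yaml")["rules"]
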