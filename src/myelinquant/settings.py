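"""Named settings profiles: one YAML file per complete parameter set.

A profile captures every pipeline parameter, so sharing the file (or just
its name and content hash, which every output CSV carries) reproduces an
analysis exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import yaml

from .background import BackgroundSettings
from .metrics import PipelineSettings
from .myelin import FrangiParams, MyelinSegSettings
from .neurite import NeuriteSegSettings


class ProfileNotFoundError(FileNotFoundError):
    pass


def settings_to_dict(settings: PipelineSettings) -> dict:
    d = dataclasses.asdict(settings)
    d["myelin"]["frangi"]["scales"] = [float(s) for s in settings.myelin.frangi.scales]
    return d


def settings_from_dict(d: dict) -> PipelineSettings:
    d = dict(d)
    frangi = FrangiParams(**d["myelin"].pop("frangi"))
    frangi.scales = tuple(frangi.scales)
    myelin = MyelinSegSettings(frangi=frangi, **d["myelin"])
    background = BackgroundSettings(**d["background"])
    neurite = NeuriteSegSettings(**d["neurite"])
    s = PipelineSettings(
        profile_name=d.get("profile_name", "default"),
        background=background,
        myelin=myelin,
        neurite=neurite,
        neurite_suffix=d.get("neurite_suffix", "_neurite"),
        myelin_suffix=d.get("myelin_suffix", "_myelin"),
    )
    s.validate()
    return s


def settings_hash(settings: PipelineSettings) -> str:
    """Short content hash identifying the exact parameter values."""
    payload = yaml.safe_dump(settings_to_dict(settings), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def save_profile(settings: PipelineSettings, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(settings_to_dict(settings), fh, sort_keys=False)
    return path


def load_profile(path: str | Path) -> PipelineSettings:
    """Load a profile YAML; a missing file lists the profiles next to it."""
    path = Path(path)
    if not path.exists():
        siblings = sorted(p.name for p in path.parent.glob("*.yaml")) if path.parent.exists() else []
        raise ProfileNotFoundError(
            f"profile {path} not found; available profiles in {path.parent}: "
            f"{siblings if siblings else 'none'}"
        )
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return settings_from_dict(data)


def default_settings(profile_name: str = "default") -> PipelineSettings:
    """The built-in default profile; needs no file on disk."""
    return PipelineSettings(profile_name=profile_name)
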