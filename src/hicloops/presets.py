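"""Named parameter presets for loop calling.

Each preset bundles every tunable of the pipeline under the parameter names
used throughout: ``q`` (upper quantile of per-diagonal values retained for
the background fit), ``adjust_by_scale``, ``q_value_trhd``,
``scaling_q_value_trhd``, ``min_cluster``, and the filter thresholds
``filter_zeros`` / ``filter_PA`` / ``filter_APA`` / ``filter_intensity``
(``None`` disables a filter).

The named presets mirror published per-species settings for GM12878 (human),
CH-12LX (mouse), C. elegans and S. cerevisiae Hi-C maps; ``default`` keeps
every optional stage off (q-threshold 0.1, scale adjustment off, minimum
cluster size 3, brightest-pixel centres, no filters).
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

__all__ = ["Preset", "PRESETS", "get_preset", "load_preset_file"]


@dataclass(frozen=True)
class Preset:
    q: float = 0.95
    adjust_by_scale: bool = False
    q_value_trhd: float = 0.1
    scaling_q_value_trhd: float = 0.1
    min_cluster: int = 3
    center_method: str = "brightest"
    filter_zeros: int | None = None
    filter_PA: float | None = None
    filter_APA: float | None = None
    filter_intensity: float | None = None
    decay_required: bool = False
    random_enrichment_min: float | None = None
    n_random: int = 100
    max_distance: int | None = None
    include_zeros: bool = False
    bh_scope: str = "diagonal"
    connectivity: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.q <= 1:
            raise ValueError("q (fit quantile) must be in (0, 1]")
        if not 0 < self.q_value_trhd <= 1:
            raise ValueError("q_value_trhd must be in (0, 1]")
        if not 0 < self.scaling_q_value_trhd <= 1:
            raise ValueError("scaling_q_value_trhd must be in (0, 1]")
        if self.min_cluster < 1:
            raise ValueError("min_cluster must be >= 1")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def with_overrides(self, **kwargs) -> "Preset":
        unknown = set(kwargs) - {f.name for f in fields(self)}
        if unknown:
            raise ValueError(f"unknown preset keys: {sorted(unknown)}")
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})


PRESETS: dict[str, Preset] = {
    "default": Preset(),
    # 5 & 10 kb human GM12878 maps
    "human-gm12878": Preset(
        q=0.95,
        adjust_by_scale=True,
        q_value_trhd=0.2,
        scaling_q_value_trhd=0.2,
        min_cluster=2,
        filter_zeros=2,
        filter_PA=1.0,
        filter_APA=1.9,
        filter_intensity=0.3,
    ),
    # 10 kb mouse CH-12LX maps
    "mouse-ch12lx": Preset(
        q=0.95,
        adjust_by_scale=True,
        q_value_trhd=0.1,
        scaling_q_value_trhd=0.05,
        min_cluster=3,
        filter_zeros=2,
        filter_PA=1.0,
        filter_APA=1.8,
        filter_intensity=0.1,
    ),
    # 5 & 10 kb C. elegans maps
    "celegans": Preset(
        q=0.95,
        adjust_by_scale=False,
        q_value_trhd=0.05,
        min_cluster=2,
        filter_zeros=2,
        filter_PA=1.0,
        filter_APA=1.7,
        filter_intensity=0.1,
    ),
    # S. cerevisiae maps (no APA/PA filtering)
    "yeast": Preset(
        q=0.95,
        adjust_by_scale=False,
        q_value_trhd=0.01,
        min_cluster=3,
        filter_zeros=2,
        filter_intensity=0.1,
    ),
}


def get_preset(name: str) -> Preset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


_BOOL = {"true": True, "false": False, "1": True, "0": False,
         "yes": True, "no": False, "none": None, "off": None}


def load_preset_file(path: str) -> Preset:
    """Read a flat ``key = value`` preset file (# comments allowed)."""
    kwargs: dict = {}
    types = {f.name: f.type for f in fields(Preset)}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in types:
                raise ValueError(f"unknown preset key {key!r}")
            low = raw.lower()
            if low in _BOOL:
                kwargs[key] = _BOOL[low]
            else:
                try:
                    kwargs[key] = int(raw)
                except ValueError:
                    try:
                        kwargs[key] = float(raw)
                    except ValueError:
                        kwargs[key] = raw
    return Preset().with_overrides(**kwargs)
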