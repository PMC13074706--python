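"""Dataset manifests: per-class sample counts and scene assignment."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .._rng import spawn
from .species import DEFAULT_SPECIES

__all__ = ["DatasetManifest", "ManifestRow", "DEFAULT_CLASS_COUNTS",
           "generate_manifest"]

# Default per-class (total, viable, non_viable) counts of the reference
# 12-class seed collection: 6005 samples, 3077 viable / 2928 non-viable.
DEFAULT_CLASS_COUNTS: dict[str, tuple[int, int, int]] = {
    "C01": (495, 255, 240),
    "C02": (512, 268, 244),
    "C03": (508, 272, 236),
    "C04": (486, 238, 248),
    "C05": (503, 261, 242),
    "C06": (492, 248, 244),
    "C07": (515, 285, 230),
    "C08": (488, 250, 238),
    "C09": (497, 246, 251),
    "C10": (506, 264, 242),
    "C11": (485, 230, 255),
    "C12": (518, 260, 258),
}

_CLASS_NAMES = {s.class_id: s.class_name for s in DEFAULT_SPECIES}


@dataclass(frozen=True)
class ManifestRow:
    sample_id: str
    class_id: str
    class_name: str
    viability: str  # "viable" | "non_viable"
    scene_id: str


@dataclass
class DatasetManifest:
    rows: list[ManifestRow]
    class_counts: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def n_viable(self) -> int:
        return sum(1 for r in self.rows if r.viability == "viable")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])

    def validate(self) -> None:
        ids = [r.sample_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids are not unique")
        for cid, (total, viable, nonviable) in self.class_counts.items():
            if viable + nonviable != total:
                raise ValueError(f"{cid}: viable + non_viable != total")


def generate_manifest(class_counts: dict[str, tuple[int, int, int]] | None = None,
                      seed: int = 0, seeds_per_scene: int = 50) -> DatasetManifest:
    """Enumerate sample rows for the requested per-class counts.

    Rows are shuffled deterministically and chunked into scenes of
    ``seeds_per_scene`` seeds (the acquisition geometry images roughly 50
    seeds per frame).  Counts may be given as ``(total, viable, non_viable)``
    or ``(total, viable)``.

    Raises
    ------
    ValueError
        If any count is negative or viable exceeds total.
    """
    if class_counts is None:
        class_counts = DEFAULT_CLASS_COUNTS
    norm: dict[str, tuple[int, int, int]] = {}
    for cid, counts in class_counts.items():
        if len(counts) == 2:
            total, viable = counts
            nonviable = total - viable
        else:
            total, viable, nonviable = counts
        if min(total, viable, nonviable) < 0:
            raise ValueError(f"{cid}: negative count")
        if viable + nonviable != total:
            raise ValueError(f"{cid}: viable ({viable}) + non_viable ({nonviable}) "
                             f"!= total ({total})")
        norm[cid] = (total, viable, nonviable)

    rows: list[tuple[str, str, str]] = []
    for cid in sorted(norm):
        total, viable, _ = norm[cid]
        name = _CLASS_NAMES.get(cid, cid)
        for i in range(total):
            viability = "viable" if i < viable else "non_viable"
            rows.append((f"{cid}-{i + 1:04d}", cid, viability))

    rng = spawn(seed, "manifest")
    order = rng.permutation(len(rows))
    manifest_rows = []
    for pos, idx in enumerate(order):
        sid, cid, viability = rows[idx]
        scene = f"S{pos // max(seeds_per_scene, 1) + 1:04d}"
        manifest_rows.append(ManifestRow(
            sample_id=sid, class_id=cid,
            class_name=_CLASS_NAMES.get(cid, cid),
            viability=viability, scene_id=scene))
    manifest = DatasetManifest(rows=manifest_rows, class_counts=norm)
    manifest.validate()
    return manifest
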