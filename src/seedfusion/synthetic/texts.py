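"""Encyclopedic-style text descriptions for each seed class.

Real seed corpora pair each category with a handful (5-10) of short natural
language descriptions covering shape, coat colour, surface pattern and
taxon.  The generator composes the class's attribute fragments through a
bank of sentence templates in varied orders, yielding distinct strings.
"""

from __future__ import annotations

from .._rng import spawn
from .species import DEFAULT_SPECIES, SpeciesSpec, species_by_id

__all__ = ["generate_texts", "generate_corpus"]

_TEMPLATES = (
    "a {shape} seed with a {coat} and {pattern}, belonging to {taxon}",
    "the seed is {shape}; its {coat} shows {pattern} ({taxon})",
    "{taxon} seed: {shape}, {coat}, {pattern}",
    "this {taxon} grain appears {shape} with {pattern} over a {coat}",
    "seed of {taxon}, {shape} in outline, {coat}, marked by {pattern}",
    "a {shape} grain whose {coat} carries {pattern}; species {taxon}",
    "{shape} seed morphology, {coat} colouring and {pattern}, typical of {taxon}",
    "coat: {coat}; outline: {shape}; surface: {pattern}; taxon: {taxon}",
    "typical {taxon} sample, {shape} form, {coat} with {pattern}",
    "described as {shape}, showing a {coat} and {pattern}, identified as {taxon}",
    "field guide entry for {taxon}: {shape} seed, {coat}, {pattern}",
    "a grain of {taxon} with {shape} geometry, {coat} tone and {pattern}",
)


def generate_texts(class_id: str, n_variants: int, seed: int = 0,
                   table: tuple[SpeciesSpec, ...] = DEFAULT_SPECIES) -> list[str]:
    """``n_variants`` distinct descriptions for one class.

    Raises ``KeyError`` for an unknown class and ``ValueError`` when more
    variants are requested than the template bank can provide.
    """
    spec = species_by_id(class_id, table)
    if n_variants > len(_TEMPLATES):
        raise ValueError(
            f"at most {len(_TEMPLATES)} distinct variants available")
    rng = spawn(seed, "texts", class_id)
    order = rng.permutation(len(_TEMPLATES))[:n_variants]
    texts = [_TEMPLATES[i].format(**spec.text_attributes) for i in order]
    assert len(set(texts)) == len(texts)
    return texts


def generate_corpus(n_variants: int = 6, seed: int = 0,
                    table: tuple[SpeciesSpec, ...] = DEFAULT_SPECIES,
                    ) -> dict[str, list[str]]:
    """Per-class description lists for the whole species table."""
    return {s.class_id: generate_texts(s.class_id, n_variants, seed, table)
            for s in table}
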