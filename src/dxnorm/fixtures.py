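"""Seeded synthetic-data generation: lexica and annotated corpora.

Every stage of the pipeline can be exercised without licensed vocabularies
or benchmark corpora: :func:`gen_lexicon` builds a MeSH-shaped concept
lexicon from a closed vocabulary, and :func:`gen_corpus` plants mentions of
those concepts in template documents using the surface-variant families the
normaliser is designed to resolve — exact names, token-reordered and
stop-word-inserted variants, Greek/Latin compounds invertible through the
bundled root lexicon, and character-edit perturbations at a controlled
rate. All output is deterministic per seed (one ``random.Random``, no
hash-order dependence).
"""

from __future__ import annotations

import random
from typing import Sequence

from .dictionary import LexiconRecord, compile_dictionary
from .io_formats import Document, Mention
from .textnorm import CanonConfig, canonicalize

__all__ = ["gen_lexicon", "gen_corpus", "COMPOSABLE_TERMS"]

# Closed name vocabulary. The adjectives are deliberately disjoint from the
# English glosses of the bundled root lexicon, so a gloss phrase generated
# by translation can only collide with the concept it was planted for.
_MODIFIERS = ["", "chronic", "acute", "congenital", "familial", "recurrent"]
_ADJECTIVES = [
    "cardiac", "renal", "hepatic", "pulmonary", "gastric", "ocular",
    "lymphatic", "pancreatic", "cranial", "biliary", "adrenal", "pleural",
    "tracheal", "retinal", "femoral", "cervical", "lumbar", "thoracic",
    "dermal", "parotid", "duodenal", "bronchiolar", "alveolar", "aortic",
]
_NOUNS = [
    "disease", "syndrome", "disorder", "deficiency", "fibrosis",
    "carcinoma", "lesion", "anomaly", "malformation", "insufficiency",
    "hyperplasia", "infection",
]

#: Greek/Latin compounds paired with the gloss phrase their decomposition
#: yields under the bundled root lexicon. A corpus planting the compound as
#: a mention of the gloss-named concept is invertible by translation.
COMPOSABLE_TERMS: list[tuple[str, str]] = [
    ("neuropathy", "nervous disease"),
    ("cardiopathy", "heart disease"),
    ("hepatopathy", "liver disease"),
    ("encephalopathy", "brain disease"),
    ("myopathy", "muscle disease"),
    ("nephritis", "kidney inflammation"),
    ("gastritis", "stomach inflammation"),
    ("dermatitis", "skin inflammation"),
    ("bronchitis", "airway inflammation"),
    ("phlebitis", "vein inflammation"),
    ("arthralgia", "joint pain"),
    ("osteopenia", "bone deficiency"),
    ("cardiomegaly", "heart enlargement"),
    ("splenomegaly", "spleen enlargement"),
    ("osteomalacia", "bone softening"),
]

_TREE_PREFIXES = ["C", "C", "F", "D"]  # mostly Diseases, some F/D for filtering


def gen_lexicon(
    n_concepts: int, synonyms_per: int = 2, seed: int = 0
) -> list[LexiconRecord]:
    """Generate a synthetic concept lexicon.

    Returns ``n_concepts * (1 + synonyms_per)`` records: each concept has a
    preferred name plus ``synonyms_per`` surface variants sharing its
    canonical form. Roughly every fifth concept is named by a root-compound
    gloss phrase (e.g. "heart disease"), so corpora can plant invertible
    compounds ("cardiopathy"). Canonical forms are unique across concepts.
    """
    if n_concepts < 1:
        raise ValueError("n_concepts must be >= 1")
    rng = random.Random(seed)
    cfg = CanonConfig()

    combos = [
        f"{m} {a} {n}".strip()
        for m in _MODIFIERS
        for a in _ADJECTIVES
        for n in _NOUNS
    ]
    rng.shuffle(combos)
    gloss_names = [phrase for _, phrase in COMPOSABLE_TERMS]
    rng.shuffle(gloss_names)

    records: list[LexiconRecord] = []
    seen_canonical: set[str] = set()
    combo_iter = iter(combos)
    made = 0
    while made < n_concepts:
        if made % 5 == 2 and gloss_names:
            name = gloss_names.pop()
        else:
            name = next(combo_iter)
        canonical = canonicalize(name, cfg)
        if not canonical or canonical in seen_canonical:
            continue
        seen_canonical.add(canonical)
        cid = f"D{made + 1:06d}"
        prefix = _TREE_PREFIXES[made % len(_TREE_PREFIXES)]
        trees = (f"{prefix}{(made % 23) + 1:02d}.{rng.randint(100, 999)}",)
        records.append(LexiconRecord(cid, name, trees))
        tokens = name.split()
        variants = [
            " ".join(reversed(tokens)),
            f"{tokens[-1]} of the {' '.join(tokens[:-1])}" if len(tokens) > 1 else f"the {name}",
            f"the {name}",
            f"{tokens[-1]} in {' '.join(tokens[:-1])}" if len(tokens) > 1 else f"{name} by the",
        ]
        for k in range(synonyms_per):
            records.append(LexiconRecord(cid, variants[k % len(variants)], trees))
        made += 1
    return records


def _perturb(surface: str, rate: float, rng: random.Random) -> str:
    """Independent per-character edits (substitute/delete/insert) at *rate*."""
    if rate <= 0:
        return surface
    out: list[str] = []
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for ch in surface:
        if rng.random() < rate:
            op = rng.choice(("sub", "del", "ins"))
            if op == "sub":
                out.append(rng.choice(alphabet))
            elif op == "ins":
                out.append(ch)
                out.append(rng.choice(alphabet))
            # "del": drop the character
        else:
            out.append(ch)
    return "".join(out) or surface


def gen_corpus(
    lexicon: Sequence[LexiconRecord],
    n_docs: int,
    perturbation: float = 0.0,
    seed: int = 0,
    mentions_per_doc: int = 5,
) -> list[Document]:
    """Generate annotated documents with planted, gold-identified mentions.

    Mention surfaces cycle through variant families: the exact preferred
    name, a token-reordered form, a stop-word-inserted form, and — for
    concepts named by a root-compound gloss — the compound itself
    (e.g. "cardiopathy" for "heart disease"). Character-edit perturbation
    is then applied at the given per-character rate. Deterministic per
    seed; output documents are valid under both PubTator and BioC writers.
    """
    if not lexicon:
        raise ValueError("lexicon must be non-empty")
    if not 0.0 <= perturbation <= 1.0:
        raise ValueError("perturbation must be in [0, 1]")
    rng = random.Random(seed)
    cfg = CanonConfig()

    # preferred name per concept (first record wins) and compound inversions
    preferred: dict[str, str] = {}
    for rec in lexicon:
        preferred.setdefault(rec.concept_id, rec.name)
    compound_for: dict[str, str] = {}
    gloss_lookup = {canonicalize(phrase, cfg): word for word, phrase in COMPOSABLE_TERMS}
    for cid, name in preferred.items():
        word = gloss_lookup.get(canonicalize(name, cfg))
        if word is not None:
            compound_for[cid] = word

    concept_ids = sorted(preferred)
    docs: list[Document] = []
    variant_cycle = 0
    for di in range(n_docs):
        doc_id = f"{10_000_000 + seed % 1000 * 10_000 + di}"
        chosen = [concept_ids[rng.randrange(len(concept_ids))] for _ in range(mentions_per_doc)]
        surfaces: list[str] = []
        for cid in chosen:
            name = preferred[cid]
            tokens = name.split()
            kinds = ["exact", "reordered", "stopword"]
            if cid in compound_for:
                kinds.append("compound")
            kind = kinds[variant_cycle % len(kinds)]
            variant_cycle += 1
            if kind == "reordered" and len(tokens) > 1:
                surface = " ".join(reversed(tokens))
            elif kind == "stopword" and len(tokens) > 1:
                surface = f"{tokens[-1]} of the {' '.join(tokens[:-1])}"
            elif kind == "compound":
                surface = compound_for[cid]
            else:
                surface = name
            surfaces.append(_perturb(surface, perturbation, rng))

        title = f"A clinical study of {surfaces[0]} in adults."
        title_prefix = "A clinical study of "
        mentions = [
            Mention(
                doc_id,
                len(title_prefix),
                len(title_prefix) + len(surfaces[0]),
                surfaces[0],
                "Disease",
                chosen[0],
            )
        ]
        abstract_parts: list[str] = []
        pos = len(title) + 1  # single separator char after the title
        for cid, surface in zip(chosen[1:], surfaces[1:]):
            lead = "Patients presenting with "
            sentence = f"{lead}{surface} were examined."
            begin = pos + len(lead)
            mentions.append(
                Mention(doc_id, begin, begin + len(surface), surface, "Disease", cid)
            )
            abstract_parts.append(sentence)
            pos += len(sentence) + 1
        abstract = " ".join(abstract_parts) or "No further findings were recorded."
        doc = Document(
            doc_id=doc_id,
            passages=[(0, title), (len(title) + 1, abstract)],
            mentions=mentions,
        )
        doc.validate()
        docs.append(doc)
    return docs


def recovery_rate(
    docs: Sequence[Document],
    lexicon: Sequence[LexiconRecord],
    params=None,
) -> float:
    """Fraction of planted mentions whose top-1 normalisation recovers the
    true concept ID (convenience wrapper for recovery experiments)."""
    from .normalizer import NormalizationParams, normalize_mention
    from .rootlex import bundled_root_lexicon

    d = compile_dictionary(lexicon)
    roots = bundled_root_lexicon()
    params = params or NormalizationParams()
    total = hit = 0
    for doc in docs:
        for m in doc.mentions:
            total += 1
            res = normalize_mention(m.text, d, roots, params)
            if res.concept_id == m.concept_id:
                hit += 1
    return hit / total if total else 0.0
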