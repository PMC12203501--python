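"""Knowledge graphs over proteins and GO terms, and their embeddings.

The graph holds (head, relation, tail) triples in which heads are tagged
proteins or GO terms and tails are GO terms, each GO term categorized as
cellular component (CC), molecular function (MF) or biological process
(BP) and carrying an annotation text.  Four standard scoring functions
measure triple plausibility as a distance d (lower = more plausible):

* TransE:   d = ||h + r - t||_2
* RotatE:   d = ||h o r - t||_2 with r a unit-modulus complex rotation
* PairRE:   d = ||h' o r_H - t' o r_T||_2 with L2-normalized entities
* ComplEx:  d = -Re<h, r, conj(t)>  (a similarity, negated)

Protein entities are not stored as free embeddings: during joint training
their representation is the adapted fused image feature of the current
cell, and at prediction time a protein's *knowledge feature* is recovered
from its protein-GO triples by inverting each scoring function for the
head and average-pooling the implied heads.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .layers import Linear, Module, Parameter

__all__ = [
    "KnowledgeGraph",
    "KGEModel",
    "HashingTextEmbedder",
    "filter_sproteinkg",
    "score_triple",
    "invert_head",
    "knowledge_feature",
    "sample_negatives",
    "embed_go_terms",
    "read_triples",
    "write_triples",
]

GO_CATEGORIES = ("CC", "MF", "BP")
KGE_METHODS = ("transe", "rotate", "pairre", "complex")


@dataclass
class KnowledgeGraph:
    entities: dict[str, str]  # entity_id -> category in {protein, CC, MF, BP}
    relations: list[str]
    triples: list[tuple[str, str, str]]
    go_texts: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        rel_set = set(self.relations)
        seen = set()
        for h, r, t in self.triples:
            if h not in self.entities or t not in self.entities:
                raise ValueError(f"triple ({h}, {r}, {t}) uses unknown entity")
            if r not in rel_set:
                raise ValueError(f"triple ({h}, {r}, {t}) uses unknown relation")
            if self.entities[h] == "protein" and self.entities[t] == "protein":
                raise ValueError(f"protein-protein triple not allowed: ({h},{r},{t})")
            if self.entities[t] == "protein":
                raise ValueError(f"protein entity {t} appears as a tail")
            if (h, r, t) in seen:
                raise ValueError(f"duplicate triple ({h}, {r}, {t})")
            seen.add((h, r, t))

    def category_members(self, category: str) -> list[str]:
        return sorted(e for e, c in self.entities.items() if c == category)

    def go_entities(self) -> list[str]:
        return sorted(e for e, c in self.entities.items() if c != "protein")

    def protein_go_triples(self) -> list[tuple[str, str, str]]:
        return [
            (h, r, t)
            for h, r, t in self.triples
            if self.entities[h] == "protein" and self.entities[t] != "protein"
        ]

    def go_go_triples(self) -> list[tuple[str, str, str]]:
        return [
            (h, r, t)
            for h, r, t in self.triples
            if self.entities[h] != "protein" and self.entities[t] != "protein"
        ]

    def triples_for_protein(self, protein_id: str) -> list[tuple[str, str, str]]:
        return [tr for tr in self.protein_go_triples() if tr[0] == protein_id]


def filter_sproteinkg(graph: KnowledgeGraph, tagged_proteins: set[str]
                      ) -> KnowledgeGraph:
    """Restrict a graph to the tagged-protein neighbourhood.

    Protein-GO triples survive iff their head is a tagged protein.  GO-GO
    triples survive iff *both* GO endpoints are related — via the kept
    protein-GO triples — to strictly more than two tagged proteins.
    Entities that no surviving triple touches are dropped.
    """
    tagged = set(tagged_proteins)
    if not tagged:
        warnings.warn("empty tagged-protein set: all protein-GO triples drop")
    kept_pg = [tr for tr in graph.protein_go_triples() if tr[0] in tagged]
    go_degree: dict[str, set[str]] = {}
    for h, _, t in kept_pg:
        go_degree.setdefault(t, set()).add(h)
    kept_gg = [
        (h, r, t)
        for h, r, t in graph.go_go_triples()
        if len(go_degree.get(h, ())) > 2 and len(go_degree.get(t, ())) > 2
    ]
    kept = kept_pg + kept_gg
    used = {e for h, _, t in kept for e in (h, t)}
    entities = {e: c for e, c in graph.entities.items() if e in used}
    relations = sorted({r for _, r, _ in kept})
    go_texts = {e: txt for e, txt in graph.go_texts.items() if e in used}
    return KnowledgeGraph(entities=entities, relations=relations,
                          triples=kept, go_texts=go_texts)


# -- triple / text I/O --------------------------------------------------------


def write_triples(graph: KnowledgeGraph, triples_path, categories_path=None,
                  texts_path=None) -> None:
    with open(triples_path, "w") as fh:
        for h, r, t in graph.triples:
            fh.write(f"{h}\t{r}\t{t}\n")
    if categories_path is not None:
        with open(categories_path, "w") as fh:
            for e in sorted(graph.entities):
                fh.write(f"{e}\t{graph.entities[e]}\n")
    if texts_path is not None:
        with open(texts_path, "w") as fh:
            for e in sorted(graph.go_texts):
                fh.write(f"{e}\t{graph.go_texts[e]}\n")


def read_triples(triples_path, categories_path, texts_path=None
                 ) -> KnowledgeGraph:
    entities: dict[str, str] = {}
    with open(categories_path) as fh:
        for line in fh:
            if line.strip():
                e, c = line.rstrip("\n").split("\t")
                entities[e] = c
    triples: list[tuple[str, str, str]] = []
    with open(triples_path) as fh:
        for line in fh:
            if line.strip():
                h, r, t = line.rstrip("\n").split("\t")
                triples.append((h, r, t))
    go_texts: dict[str, str] = {}
    if texts_path is not None:
        with open(texts_path) as fh:
            for line in fh:
                if line.strip():
                    e, txt = line.rstrip("\n").split("\t", 1)
                    go_texts[e] = txt
    relations = sorted({r for _, r, _ in triples})
    return KnowledgeGraph(entities=entities, relations=relations,
                          triples=triples, go_texts=go_texts)


# -- text embedding -----------------------------------------------------------


class HashingTextEmbedder:
    """Deterministic character-trigram hashing embedder.

    A lightweight, dependency-free stand-in for a pre-trained biomedical
    text encoder: trigram counts are hashed (crc32, seed-salted) into
    ``dim`` buckets with a pseudo-random sign, then L2-normalized.  Any
    object with the same ``dim``/``embed`` interface (e.g. a transformer
    encoder) can be plugged in instead.
    """

    def __init__(self, dim: int = 64, seed: int = 0):
        self.dim = int(dim)
        self.seed = int(seed)

    def embed(self, texts: list[str]) -> np.ndarray:
        out = np.zeros((len(texts), self.dim), dtype=np.float64)
        # crc32 is linear, so a plain salt would shift every hash by the
        # same constant; mix the seed in multiplicatively instead
        mix = (self.seed * 0x9E3779B9 + 0x7F4A7C15) & 0xFFFFFFFF
        for i, text in enumerate(texts):
            data = text.lower().encode()
            for j in range(len(data) - 2):
                h = zlib.crc32(data[j : j + 3])
                h = ((h ^ mix) * 2654435761) & 0xFFFFFFFF
                sign = 1.0 if (h >> 16) & 1 else -1.0
                out[i, h % self.dim] += sign
            norm = np.linalg.norm(out[i])
            if norm > 0:
                out[i] /= norm
        return out


def embed_go_terms(graph: KnowledgeGraph, embedder,
                   adapter: Linear | None = None) -> dict[str, np.ndarray]:
    """Text-initialized vectors for every GO entity (adapter optional)."""
    gos = graph.go_entities()
    missing = [e for e in gos if e not in graph.go_texts]
    if missing:
        raise ValueError(f"GO entities without annotation text: {missing}")
    vecs = embedder.embed([graph.go_texts[e] for e in gos])
    if adapter is not None:
        vecs = adapter(Tensor(vecs)).data
    return {e: vecs[i] for i, e in enumerate(gos)}


# -- scoring functions --------------------------------------------------------

_EPS_NORM = 1e-12   # guards divisions (entity normalization)
_EPS_DIST = 1e-30   # guards the sqrt in distances; floor is 1e-15


def _split(x: Tensor) -> tuple[Tensor, Tensor]:
    d = x.shape[-1]
    if d % 2:
        raise ValueError("entity_dim must be even for complex pairing")
    return x[..., : d // 2], x[..., d // 2 :]


def _l2(x: Tensor, axis: int = -1) -> Tensor:
    return ((x * x).sum(axis=axis) + _EPS_DIST) ** 0.5


def _l2_normalize(x: Tensor) -> Tensor:
    n = ((x * x).sum(axis=-1, keepdims=True) + _EPS_NORM) ** 0.5
    return x / n


def score_batch(method: str, h: Tensor, r: Tensor, t: Tensor, *,
                h_normalized: bool = False, t_normalized: bool = False,
                norm: str = "l2") -> Tensor:
    """Vectorized distance d for (M, d) heads/relations/tails.

    Lower d means a more plausible triple for all four methods (the
    ComplEx trilinear similarity is negated).  For PairRE, entities are
    L2-normalized here unless flagged as already normalized — implied
    heads produced by :func:`invert_head` live in the normalized space
    and must be passed with ``h_normalized=True``.
    """
    if method == "transe":
        diff = h + r - t
        if norm == "l1":
            return ((diff * diff + _EPS_DIST) ** 0.5).sum(axis=-1)
        return _l2(diff)
    if method == "rotate":
        hre, him = _split(h)
        tre, tim = _split(t)
        cos, sin = _cos(r), _sin(r)
        rot_re = hre * cos - him * sin
        rot_im = hre * sin + him * cos
        return (
            ((rot_re - tre) ** 2).sum(axis=-1)
            + ((rot_im - tim) ** 2).sum(axis=-1)
            + _EPS_DIST
        ) ** 0.5
    if method == "pairre":
        rh, rt = _split(r)
        hh = h if h_normalized else _l2_normalize(h)
        tt = t if t_normalized else _l2_normalize(t)
        return _l2(hh * rh - tt * rt)
    if method == "complex":
        hre, him = _split(h)
        rre, rim = _split(r)
        tre, tim = _split(t)
        real = (hre * rre * tre + hre * rim * tim
                + him * rre * tim - him * rim * tre)
        return -real.sum(axis=-1)
    raise ValueError(f"unknown KGE method {method!r}; choose from {KGE_METHODS}")


def _cos(x: Tensor) -> Tensor:
    out = Tensor._make(np.cos(x.data), (x,),
                       lambda g: x._accumulate(-g * np.sin(x.data)))
    return out


def _sin(x: Tensor) -> Tensor:
    out = Tensor._make(np.sin(x.data), (x,),
                       lambda g: x._accumulate(g * np.cos(x.data)))
    return out


def invert_head_batch(method: str, r: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Implied head vectors solving d(h, r, t) = 0 for (M, d) arrays."""
    r = np.atleast_2d(np.asarray(r, dtype=np.float64))
    t = np.atleast_2d(np.asarray(t, dtype=np.float64))
    if method == "transe":
        return t - r
    if method == "rotate":
        d = t.shape[-1]
        tre, tim = t[..., : d // 2], t[..., d // 2 :]
        cos, sin = np.cos(r), np.sin(r)
        # rotate t by the inverse (conjugate) rotation
        hre = tre * cos + tim * sin
        him = tim * cos - tre * sin
        return np.concatenate([hre, him], axis=-1)
    if method == "pairre":
        d = t.shape[-1]
        rh, rt = r[..., :d], r[..., d:]
        small = np.abs(rh) <= 1e-8
        if small.any():
            coord = tuple(np.argwhere(small)[0])
            raise ValueError(
                f"PairRE head inversion undefined: |r_H| <= 1e-8 at "
                f"coordinate {coord}"
            )
        tt = t / np.maximum(np.linalg.norm(t, axis=-1, keepdims=True), _EPS_NORM)
        return tt * rt / rh
    if method == "complex":
        raise ValueError(
            "ComplEx has no exact head inversion; knowledge_feature pools "
            "t o conj(r) as a documented surrogate"
        )
    raise ValueError(f"unknown KGE method {method!r}; choose from {KGE_METHODS}")


def _complex_surrogate(r: np.ndarray, t: np.ndarray) -> np.ndarray:
    """t o conj(r): the rotation-style surrogate head used for ComplEx."""
    d = t.shape[-1]
    tre, tim = t[..., : d // 2], t[..., d // 2 :]
    rre, rim = r[..., : d // 2], r[..., d // 2 :]
    return np.concatenate(
        [tre * rre + tim * rim, tim * rre - tre * rim], axis=-1
    )


# -- the embedding model ------------------------------------------------------


class KGEModel(Module):
    """Scoring-function choice plus GO/relation embeddings and adapters.

    GO embeddings are initialized from annotation-text features through a
    learned linear adapter and remain trainable; relation parameters are
    free.  ``protein_adapter`` maps the fused image feature to entity_dim
    so cells can stand in for their protein's head entity during joint
    training.
    """

    def __init__(self, method: str, graph: KnowledgeGraph, *,
                 entity_dim: int = 16, fused_dim: int = 768,
                 gamma: float = 6.0, n_negatives: int = 8,
                 text_embedder=None, seed: int = 0):
        super().__init__()
        method = method.lower()
        if method not in KGE_METHODS:
            raise ValueError(f"unknown KGE method {method!r}")
        if method in ("rotate", "complex") and entity_dim % 2:
            raise ValueError(f"{method} requires an even entity_dim")
        if gamma <= 0 or n_negatives < 1:
            raise ValueError("gamma must be > 0 and n_negatives >= 1")
        self.method = method
        self.entity_dim = int(entity_dim)
        self.gamma = float(gamma)
        self.n_negatives = int(n_negatives)
        rng = np.random.default_rng(seed)

        self.go_ids = graph.go_entities()
        self.go_index = {e: i for i, e in enumerate(self.go_ids)}
        self.go_categories = np.array(
            [graph.entities[e] for e in self.go_ids], dtype=object
        )
        self.relation_ids = list(graph.relations)
        self.relation_index = {r: i for i, r in enumerate(self.relation_ids)}

        if text_embedder is None:
            text_embedder = HashingTextEmbedder(dim=64, seed=seed)
        self.text_embedder = text_embedder
        self.text_adapter = Linear(text_embedder.dim, entity_dim, rng)
        init = embed_go_terms(graph, text_embedder, adapter=self.text_adapter)
        self.go_embeddings = Parameter(
            np.stack([init[e] for e in self.go_ids])
        )

        pdim = {"transe": entity_dim, "rotate": entity_dim // 2,
                "pairre": 2 * entity_dim, "complex": entity_dim}[method]
        if method == "rotate":
            rel = rng.uniform(-np.pi, np.pi, size=(len(self.relation_ids), pdim))
        elif method == "pairre":
            # near-unit multiplicative init keeps head inversion
            # (division by r_H) well-conditioned from the start
            rel = 1.0 + 0.1 * rng.normal(size=(len(self.relation_ids), pdim))
        else:
            rel = rng.normal(0.0, 0.5, size=(len(self.relation_ids), pdim))
        self.relation_parameters = Parameter(rel)
        self.protein_adapter = Linear(fused_dim, entity_dim, rng)

    # raw-array views -------------------------------------------------------
    def go_embedding(self, entity_id: str) -> np.ndarray:
        return self.go_embeddings.data[self.go_index[entity_id]]

    def relation_parameter(self, relation_id) -> np.ndarray:
        idx = (relation_id if isinstance(relation_id, (int, np.integer))
               else self.relation_index[relation_id])
        return self.relation_parameters.data[idx]

    def score_rows(self, h: Tensor, rel_idx: np.ndarray, t: Tensor, *,
                   h_normalized: bool = False) -> Tensor:
        r = self.relation_parameters.take_rows(rel_idx)
        return score_batch(self.method, h, r, t, h_normalized=h_normalized)


def score_triple(model: KGEModel, h_vec, r_id, t_vec, *,
                 h_normalized: bool = False, t_normalized: bool = False
                 ) -> float:
    """Distance d(h, r, t) for one triple of plain vectors."""
    h = np.asarray(h_vec, dtype=np.float64)
    t = np.asarray(t_vec, dtype=np.float64)
    if h.shape != t.shape or h.shape[-1] != model.entity_dim:
        raise ValueError(
            f"entity vectors must have dim {model.entity_dim}, got "
            f"{h.shape} and {t.shape}"
        )
    r = model.relation_parameter(r_id)
    d = score_batch(model.method, Tensor(h[None]), Tensor(r[None]),
                    Tensor(t[None]), h_normalized=h_normalized,
                    t_normalized=t_normalized)
    return float(d.data[0])


def invert_head(model: KGEModel, r_id, t_vec) -> np.ndarray:
    """Implied head for one triple (TransE / RotatE / PairRE only).

    For PairRE the result lives in the L2-normalized entity space: score
    it with ``h_normalized=True``.
    """
    r = model.relation_parameter(r_id)
    t = np.asarray(t_vec, dtype=np.float64)
    return invert_head_batch(model.method, r[None], t[None])[0]


def knowledge_feature(model: KGEModel, protein_id: str,
                      graph: KnowledgeGraph, *, pooling: str = "implied_head"
                      ) -> tuple[np.ndarray, bool]:
    """Average-pooled knowledge feature of one protein.

    Returns ``(vector, present)``; a protein with no protein-GO triples
    gets the zero vector and ``present=False``.  ``pooling`` chooses
    between averaging the implied head per triple (default) and averaging
    raw tail (GO) embeddings.
    """
    triples = graph.triples_for_protein(protein_id)
    if not triples:
        return np.zeros(model.entity_dim), False
    ts = np.stack([model.go_embedding(t) for _, _, t in triples])
    if pooling == "tail_embedding":
        return ts.mean(axis=0), True
    rs = np.stack([model.relation_parameter(r) for _, r, _ in triples])
    if model.method == "complex":
        heads = _complex_surrogate(rs, ts)
    else:
        heads = invert_head_batch(model.method, rs, ts)
    return heads.mean(axis=0), True


def sample_negatives(graph: KnowledgeGraph, triple: tuple[str, str, str],
                     n: int, rng: np.random.Generator
                     ) -> list[tuple[str, str, str]]:
    """n corrupted triples with tails drawn from the true tail's category."""
    h, r, t = triple
    category = graph.entities[t]
    members = [e for e in graph.category_members(category) if e != t]
    if not members:
        raise ValueError(
            f"cannot corrupt tail {t!r}: category {category!r} has no other "
            "members"
        )
    picks = rng.integers(0, len(members), size=n)
    return [(h, r, members[i]) for i in picks]
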