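"""Uniform contract for turning peptides into fixed-length vectors.

Backends share one interface: a declared output dimension and a deterministic
``embed(sequence) -> vector`` map. Protein-language-model backends (ProtBERT,
1024-d; ESM-2 650M, 1280-d) mean-pool last-hidden-layer token embeddings,
excluding special tokens; they require the optional ``torch`` +
``transformers`` stack and an explicit download opt-in, and raise a clear
capability error otherwise. Descriptor backends (z-scale / T-scale, 5-d) and a
hash-seeded mock backend keep the full pipeline testable offline. An on-disk
cache keyed by (backend, sequence) lets expensive embeddings be reused.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np

from simpep.descriptors import descriptor_vector
from simpep.peptide_io import CANONICAL_RESIDUES, Peptide, PeptideSet


class EmbeddingError(Exception):
    """Embedding computation failed."""


class BackendUnavailableError(EmbeddingError):
    """The backend's runtime dependencies are not installed/downloadable."""


class PoolingError(EmbeddingError):
    """No non-special tokens to pool."""


def pool_token_matrix(tokens: np.ndarray, special_mask) -> np.ndarray:
    """Arithmetic mean over token rows where ``special_mask`` is False.

    Accumulates in float64 regardless of input dtype, then casts back, so the
    pooled vector is reproducible across batch layouts.
    """
    tokens = np.asarray(tokens)
    mask = np.asarray(special_mask, dtype=bool)
    if tokens.ndim != 2 or mask.shape != (tokens.shape[0],):
        raise EmbeddingError(
            f"expected T x d matrix with T-length mask, got {tokens.shape} and {mask.shape}"
        )
    keep = ~mask
    if not keep.any():
        raise PoolingError("all tokens are special; nothing to pool")
    pooled = tokens[keep].astype(np.float64).mean(axis=0)
    return pooled.astype(tokens.dtype) if np.issubdtype(tokens.dtype, np.floating) else pooled


def _as_sequence(peptide) -> str:
    return peptide.sequence if isinstance(peptide, Peptide) else str(peptide)


class EmbeddingBackend:
    """Base class: named, fixed-dimension, deterministic per sequence."""

    name: str = "base"
    dim: int = 0
    deterministic: bool = True

    def embed_sequence(self, sequence: str) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def __repr__(self) -> str:
        return f"{type(self).__name__}(name={self.name!r}, dim={self.dim})"


class MockBackend(EmbeddingBackend):
    """Deterministic pseudo-random vectors seeded by a hash of the sequence.

    Useful for exercising every downstream stage with no model downloads; the
    vectors carry no biology.
    """

    name = "mock"

    def __init__(self, dim: int = 8):
        if dim < 1:
            raise EmbeddingError("mock backend dim must be >= 1")
        self.dim = dim

    def embed_sequence(self, sequence: str) -> np.ndarray:
        digest = hashlib.sha256(sequence.encode("utf-8")).digest()
        seed = int.from_bytes(digest[:4], "big")
        rng = np.random.default_rng(seed)
        return rng.standard_normal(self.dim)


class ScaleBackend(EmbeddingBackend):
    """Descriptor-table backend: 5-d mean-pooled z-scale or T-scale vectors."""

    dim = 5

    def __init__(self, table: str):
        self.name = table
        self._table = table

    def embed_sequence(self, sequence: str) -> np.ndarray:
        return descriptor_vector(sequence, self._table)


class PrecomputedBackend(EmbeddingBackend):
    """Lookup backend over a fixed sequence -> vector mapping.

    Used for externally computed embeddings (e.g. exported PLM vectors) and
    for synthetic embedding clouds attached to placeholder sequences.
    """

    name = "precomputed"

    def __init__(self, vectors: dict, name: str = "precomputed"):
        if not vectors:
            raise EmbeddingError("precomputed backend needs at least one vector")
        self.name = name
        self._vectors = {k: np.asarray(v, dtype=float) for k, v in vectors.items()}
        dims = {v.shape for v in self._vectors.values()}
        if len(dims) != 1 or len(next(iter(dims))) != 1:
            raise EmbeddingError(f"inconsistent vector shapes: {sorted(dims)}")
        self.dim = next(iter(dims))[0]

    def embed_sequence(self, sequence: str) -> np.ndarray:
        try:
            return self._vectors[sequence]
        except KeyError:
            raise EmbeddingError(
                f"no precomputed vector for sequence {sequence[:20]!r}..."
            ) from None


class _PLMBackend(EmbeddingBackend):
    """Shared machinery for HuggingFace masked-LM backends (per-sequence inference)."""

    model_id: str = ""

    def __init__(self, allow_download: bool = False, device: str = "cpu"):
        self.allow_download = allow_download
        self.device = device
        self._model = None
        self._tokenizer = None

    def _load(self):
        if self._model is not None:
            return
        try:
            import torch  # noqa: F401
            from transformers import AutoModel, AutoTokenizer
        except ImportError as exc:
            raise BackendUnavailableError(
                f"backend {self.name!r} needs the optional 'plm' extra "
                "(torch + transformers); install it, point at a warm cache, "
                "or use the 'mock'/'zscale'/'tscale' backends"
            ) from exc
        kwargs = {"local_files_only": not self.allow_download}
        try:
            self._tokenizer = AutoTokenizer.from_pretrained(self.model_id, **kwargs)
            self._model = AutoModel.from_pretrained(self.model_id, **kwargs).to(self.device)
            self._model.eval()
        except OSError as exc:
            raise BackendUnavailableError(
                f"weights for {self.model_id!r} are not cached locally; rerun "
                "with allow_download=True or use a cached/mock backend"
            ) from exc

    def _prepare(self, sequence: str) -> str:
        return sequence

    def embed_sequence(self, sequence: str) -> np.ndarray:
        self._load()
        import torch

        with torch.no_grad():
            enc = self._tokenizer(self._prepare(sequence), return_tensors="pt").to(self.device)
            hidden = self._model(**enc).last_hidden_state[0].cpu().numpy()
        special = self._tokenizer.get_special_tokens_mask(
            enc["input_ids"][0].tolist(), already_has_special_tokens=True
        )
        return pool_token_matrix(hidden, np.asarray(special, dtype=bool))


class ProtBertBackend(_PLMBackend):
    """Rostlab ProtBert, 1024-d last-hidden-layer mean pooling."""

    name = "protbert"
    dim = 1024
    model_id = "Rostlab/prot_bert"

    def _prepare(self, sequence: str) -> str:
        # ProtBert convention: uppercase, rare residues to X, space-separated
        mapped = [ch if ch in CANONICAL_RESIDUES else "X" for ch in sequence.upper()]
        return " ".join(mapped)


class Esm2Backend(_PLMBackend):
    """ESM-2 650M (the ESM-2 variant with hidden size 1280)."""

    name = "esm2"
    dim = 1280
    model_id = "facebook/esm2_t33_650M_UR50D"


_BACKENDS = {
    "mock": MockBackend,
    "zscale": lambda **kw: ScaleBackend("zscale"),
    "tscale": lambda **kw: ScaleBackend("tscale"),
    "protbert": ProtBertBackend,
    "esm2": Esm2Backend,
}


def get_backend(name: str, **kwargs) -> EmbeddingBackend:
    """Instantiate a backend by name: mock, zscale, tscale, protbert, esm2."""
    try:
        factory = _BACKENDS[name.lower()]
    except KeyError:
        raise EmbeddingError(f"unknown backend {name!r}; available: {sorted(_BACKENDS)}") from None
    return factory(**kwargs)


class EmbeddingCache:
    """Directory-backed vector store keyed by (backend name, sequence).

    Vectors live in ``.npy`` files named by a digest; a JSON manifest records
    the key -> file mapping. A corrupt entry is dropped with a warning and
    recomputed.
    """

    def __init__(self, directory):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)
        self._manifest_path = self.directory / "manifest.json"
        self._manifest = self._read_manifest()

    def _read_manifest(self) -> dict:
        if not self._manifest_path.exists():
            return {}
        try:
            return json.loads(self._manifest_path.read_text(encoding="utf-8"))
        except (json.JSONDecodeError, OSError):
            import logging

            logging.getLogger(__name__).warning(
                "embedding cache manifest at %s is corrupt; rebuilding", self._manifest_path
            )
            return {}

    def _key(self, backend_name: str, sequence: str) -> str:
        return hashlib.sha256(f"{backend_name}\n{sequence}".encode("utf-8")).hexdigest()

    def get(self, backend_name: str, sequence: str) -> Optional[np.ndarray]:
        key = self._key(backend_name, sequence)
        fname = self._manifest.get(key)
        if fname is None:
            return None
        try:
            return np.load(self.directory / fname)
        except (OSError, ValueError):
            import logging

            logging.getLogger(__name__).warning(
                "embedding cache entry %s is corrupt; recomputing", fname
            )
            del self._manifest[key]
            return None

    def put(self, backend_name: str, sequence: str, vector: np.ndarray) -> None:
        key = self._key(backend_name, sequence)
        fname = f"{key}.npy"
        np.save(self.directory / fname, np.asarray(vector))
        self._manifest[key] = fname
        self._manifest_path.write_text(json.dumps(self._manifest, indent=0), encoding="utf-8")


def embed(peptide, backend: EmbeddingBackend, cache: Optional[EmbeddingCache] = None) -> np.ndarray:
    """Embed one peptide, consulting the cache first when given."""
    sequence = _as_sequence(peptide)
    if cache is not None:
        hit = cache.get(backend.name, sequence)
        if hit is not None:
            return hit
    vector = np.asarray(backend.embed_sequence(sequence), dtype=float)
    if vector.shape != (backend.dim,):
        raise EmbeddingError(
            f"backend {backend.name!r} returned shape {vector.shape}, expected ({backend.dim},)"
        )
    if not np.all(np.isfinite(vector)):
        raise EmbeddingError(f"backend {backend.name!r} produced non-finite components")
    if cache is not None:
        cache.put(backend.name, sequence, vector)
    return vector


def embed_set(
    peptides: PeptideSet,
    backend: EmbeddingBackend,
    cache: Optional[EmbeddingCache] = None,
) -> np.ndarray:
    """Embed every member of a set; row order matches the set order."""
    if len(peptides) == 0:
        raise EmbeddingError("cannot embed an empty peptide set")
    return np.stack([embed(p, backend, cache=cache) for p in peptides])
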