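"""File formats: FASTA input, testing-list / sketch files, matrices, trees.

Text formats are TSV with ``#``-prefixed header lines carrying the
parameters needed to interpret the payload; every writer emits the
testing-list digest so that sketch compatibility can be enforced on read.
The optional binary sketch format packs each entry into 4 bits when
``k <= 15`` (one byte holds two entries), or one byte when ``k <= 255``.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .core import DNA, Alphabet, IncompatibleSketchError, InvalidInputError, Sequence, tokenize
from .similarity import SimilarityMatrix
from .sketch import Sketch, SketchSet, TestingList

TESTLIST_MAGIC = "#subseqsketch-testlist v1"
SKETCH_MAGIC = "#subseqsketch v1"
SKETCH_BIN_MAGIC = "#subseqsketch-bin v1"


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[Sequence]:
    """Read a (possibly multi-line, CRLF-tolerant) FASTA file.

    Ids are the first whitespace-delimited token of each header; residues
    are uppercased.  Empty files, duplicate ids and empty records are
    errors.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InvalidInputError(f"{path}: no FASTA records found")
    seqs: list[Sequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise InvalidInputError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).strip()
        if not residues:
            raise InvalidInputError(f"{path}: record {rec.id!r} has an empty sequence")
        seqs.append(Sequence(rec.id, residues))
    return seqs


def write_fasta(seqs: list[Sequence], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# testing lists


def write_testing_list(L: TestingList, path: str | Path, extra_header: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(TESTLIST_MAGIC + "\n")
        fh.write(f"#alphabet={''.join(L.alphabet.symbols)}\n")
        seed = "none" if L.seed is None else L.seed
        prov = "sampled" if L.provenance == "sampled-from-input" else "random"
        fh.write(f"#t={L.t} k={L.k} size={L.size} seed={seed} provenance={prov}\n")
        for line in extra_header or []:
            fh.write(f"#{line}\n")
        for e in L.entries:
            fh.write(str(e) + "\n")


def read_testing_list(path: str | Path) -> TestingList:
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\r\n") for ln in fh]
    if not lines or lines[0] != TESTLIST_MAGIC:
        raise InvalidInputError(f"{path}: not a testing-list file (missing magic line)")
    alphabet = DNA
    t = k = size = None
    seed: int | None = None
    provenance = "random"
    body_start = 1
    for i, ln in enumerate(lines[1:], start=1):
        if not ln.startswith("#"):
            body_start = i
            break
        if ln.startswith("#alphabet="):
            alphabet = Alphabet(tuple(ln.split("=", 1)[1]))
        elif ln.startswith("#t="):
            fields = dict(part.split("=", 1) for part in ln[1:].split())
            t, k, size = int(fields["t"]), int(fields["k"]), int(fields["size"])
            seed = None if fields.get("seed") == "none" else int(fields.get("seed", 0))
            provenance = (
                "sampled-from-input" if fields.get("provenance") == "sampled" else "random"
            )
    else:
        body_start = len(lines)
    if t is None:
        raise InvalidInputError(f"{path}: missing '#t=... k=... size=...' header")
    entries = tuple(
        tokenize(ln.strip(), t) for ln in lines[body_start:] if ln.strip()
    )
    if len(entries) != size:
        raise InvalidInputError(
            f"{path}: header promises {size} entries, found {len(entries)}"
        )
    return TestingList(entries, t, k, alphabet, seed, provenance)


# ---------------------------------------------------------------------------
# sketch files


def _entry_bits(k: int) -> int:
    if k <= 15:
        return 4
    if k <= 255:
        return 8
    raise InvalidInputError(f"binary sketch format supports k <= 255, got k={k}")


def write_sketch_file(
    S: SketchSet,
    path: str | Path,
    format: str = "tsv",
    extra_header: list[str] | None = None,
) -> None:
    """Write a sketch set; ``format`` is ``tsv`` or ``binary`` (packed
    ceil(log2(k+1))-bit entries, rounded up to 4 or 8 bits)."""
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write(SKETCH_MAGIC + "\n")
            fh.write(f"#testlist_digest={S.testing_digest}\n")
            fh.write(f"#t={S.t} k={S.k} L={S.size}\n")
            for line in extra_header or []:
                fh.write(f"#{line}\n")
            for sk in S.sketches:
                fh.write(sk.seq_id + "\t" + ",".join(map(str, sk.values)) + "\n")
    elif format == "binary":
        bits = _entry_bits(S.k)
        header = [
            SKETCH_BIN_MAGIC,
            f"#testlist_digest={S.testing_digest}",
            f"#t={S.t} k={S.k} L={S.size} n={len(S)} bits={bits}",
        ]
        header += [f"#{line}" for line in extra_header or []]
        header += [f"#id={sk.seq_id}" for sk in S.sketches]
        header.append("#data")
        with open(path, "wb") as fh:
            fh.write(("\n".join(header) + "\n").encode())
            for sk in S.sketches:
                fh.write(_pack(sk.values, bits, S.size))
    else:
        raise InvalidInputError(f"unknown sketch file format {format!r}")


def _pack(values: np.ndarray, bits: int, size: int) -> bytes:
    v = np.asarray(values, dtype=np.uint8)
    if bits == 8:
        return v.tobytes()
    if size % 2:
        v = np.concatenate([v, np.zeros(1, dtype=np.uint8)])
    return (v[0::2] | (v[1::2] << 4)).astype(np.uint8).tobytes()


def _unpack(raw: bytes, bits: int, size: int) -> np.ndarray:
    b = np.frombuffer(raw, dtype=np.uint8)
    if bits == 8:
        return b.astype(np.int64)
    lo = (b & 0x0F).astype(np.int64)
    hi = (b >> 4).astype(np.int64)
    out = np.empty(2 * len(b), dtype=np.int64)
    out[0::2] = lo
    out[1::2] = hi
    return out[:size]


def read_sketch_file(
    path: str | Path,
    testing_list: TestingList | None = None,
    force: bool = False,
) -> SketchSet:
    """Read a TSV or binary sketch file.

    If ``testing_list`` is given, its digest must match the file's unless
    ``force`` is set.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        first = fh.readline().decode().rstrip("\r\n")
        if first == SKETCH_MAGIC:
            text = first + "\n" + fh.read().decode()
            S = _read_sketch_tsv(text, path)
        elif first == SKETCH_BIN_MAGIC:
            S = _read_sketch_binary(fh, path)
        else:
            raise InvalidInputError(f"{path}: not a sketch file (missing magic line)")
    if testing_list is not None and S.testing_digest != testing_list.digest():
        if not force:
            raise IncompatibleSketchError(
                f"{path}: sketch digest {S.testing_digest} does not match the "
                f"testing list ({testing_list.digest()})"
            )
    return S


def _parse_sketch_header(ln: str) -> tuple[int, int, int, dict[str, str]]:
    fields = dict(part.split("=", 1) for part in ln[1:].split())
    return int(fields["t"]), int(fields["k"]), int(fields["L"]), fields


def _read_sketch_tsv(text: str, path: Path) -> SketchSet:
    digest = None
    t = k = size = None
    sketches: list[Sketch] = []
    for ln in text.splitlines()[1:]:
        if ln.startswith("#testlist_digest="):
            digest = ln.split("=", 1)[1]
        elif ln.startswith("#t="):
            t, k, size, _ = _parse_sketch_header(ln)
        elif ln.startswith("#") or not ln.strip():
            continue
        else:
            if digest is None or k is None:
                raise InvalidInputError(f"{path}: sketch data before header")
            seq_id, _, payload = ln.partition("\t")
            values = np.array([int(x) for x in payload.split(",")], dtype=np.int64)
            sketches.append(Sketch(seq_id, values, digest, k))
    if digest is None or t is None:
        raise InvalidInputError(f"{path}: incomplete sketch header")
    return SketchSet(digest, t, k, size, sketches)


def _read_sketch_binary(fh, path: Path) -> SketchSet:
    digest = None
    t = k = size = n = bits = None
    ids: list[str] = []
    while True:
        ln = fh.readline().decode().rstrip("\r\n")
        if ln == "#data":
            break
        if ln.startswith("#testlist_digest="):
            digest = ln.split("=", 1)[1]
        elif ln.startswith("#t="):
            t, k, size, fields = _parse_sketch_header(ln)
            n, bits = int(fields["n"]), int(fields["bits"])
        elif ln.startswith("#id="):
            ids.append(ln.split("=", 1)[1])
        elif ln == "":
            raise InvalidInputError(f"{path}: truncated binary sketch file")
    if digest is None or t is None or n is None or len(ids) != n:
        raise InvalidInputError(f"{path}: incomplete binary sketch header")
    per = math.ceil(size * bits / 8) if bits == 4 else size
    sketches = []
    for seq_id in ids:
        raw = fh.read(per)
        if len(raw) != per:
            raise InvalidInputError(f"{path}: truncated binary sketch payload")
        sketches.append(Sketch(seq_id, _unpack(raw, bits, size), digest, k))
    return SketchSet(digest, t, k, size, sketches)


# ---------------------------------------------------------------------------
# matrices and trees


def write_matrix_tsv(M: SimilarityMatrix, path: str | Path, extra_header: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in extra_header or []:
            fh.write(f"#{line}\n")
        fh.write(f"#metric={M.metric}\n")
        fh.write("\t" + "\t".join(M.col_ids) + "\n")
        for rid, row in zip(M.row_ids, M.values):
            fh.write(rid + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")


def write_phylip(M: SimilarityMatrix, path: str | Path, strict: bool = False) -> None:
    """Square PHYLIP distance matrix.

    Relaxed names (up to 250 characters, whitespace-free) by default; the
    strict mode truncates to the classic 10 characters and refuses on
    collisions.
    """
    if M.row_ids != M.col_ids:
        raise InvalidInputError("PHYLIP output needs a square matrix")
    names = []
    for rid in M.row_ids:
        name = rid.replace(" ", "_")
        if strict:
            name = name[:10]
        elif len(name) > 250:
            raise InvalidInputError(f"taxon name too long for relaxed PHYLIP: {rid!r}")
        names.append(name)
    if len(set(names)) != len(names):
        raise InvalidInputError(
            "taxon name collision after truncation; use relaxed mode"
        )
    width = max(10, max(len(x) for x in names)) + 2
    with open(path, "w") as fh:
        fh.write(f"{len(names)}\n")
        for name, row in zip(names, M.values):
            fh.write(name.ljust(width) + " ".join(f"{x:.6f}" for x in row) + "\n")


def write_newick(newick: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(newick.rstrip() + ("\n" if not newick.endswith("\n") else ""))
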