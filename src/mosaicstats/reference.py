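"""Reference-sequence access helpers (FASTA in, plain strings out)."""

from __future__ import annotations

from pathlib import Path


def as_seq_dict(reference) -> dict[str, str]:
    """Coerce a reference to ``{contig: sequence}``.

    Accepts a dict of strings, a FASTA path, or a ``pyfaidx.Fasta``.
    Sequences are uppercased once on load.
    """
    if isinstance(reference, dict):
        return reference
    if isinstance(reference, (str, Path)):
        import pyfaidx

        fa = pyfaidx.Fasta(str(reference))
        return {name: str(fa[name][:]).upper() for name in fa.keys()}
    # pyfaidx.Fasta or anything mapping-like with sequence records
    try:
        return {name: str(reference[name][:]).upper() for name in reference.keys()}
    except Exception as exc:  # pragma: no cover - defensive
        raise TypeError(f"cannot interpret reference of type {type(reference)!r}") from exc


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")
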