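"""Read mapping and per-fragment coverage/GC summary tables.

The coverage arithmetic follows the published convention for single-end
reads of fixed length: bases mapped = reads mapped x read length, fold
coverage = bases / fragment length (1 decimal), GC% over unambiguous bases
(2 decimals), and *unweighted* means across fragments (mean coverage to 1
decimal, mean GC to 3). Rounding is half-up throughout, matching how the
printed tables were produced.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .records import SequenceRecord, revcomp


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def filter_contigs_by_length(contigs: list[SequenceRecord], min_len: int
                             ) -> list[SequenceRecord]:
    """Contigs of length >= min_len (inclusive), order preserved."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [c for c in contigs if len(c.seq) >= min_len]


def map_reads(reads, fragments: list[SequenceRecord], max_mismatch: int = 2
              ) -> tuple[dict[str, int], int]:
    """Count reads mapping to each fragment with <= max_mismatch substitutions.

    A read counts for its single best placement (fewest mismatches) over
    both strands of all fragments; ties resolve to the lowest fragment id,
    leftmost position, '+' strand. Uses pigeonhole seeding: a read with at
    most k mismatches contains an exact segment of length len//(k+1).
    Returns (per-fragment counts, number of unmapped reads).
    """
    counts = {f.id: 0 for f in fragments}
    unmapped = 0
    if not fragments:
        return counts, len(list(reads))
    frag_arrays = {}
    for f in fragments:
        frag_arrays[f.id] = {
            "+": np.frombuffer(f.seq.encode(), dtype=np.uint8),
            "-": np.frombuffer(revcomp(f.seq).encode(), dtype=np.uint8),
        }
    # seed index is rebuilt per read length class lazily
    seed_cache: dict[int, dict[str, list[tuple[str, str, int]]]] = {}

    def seed_index(k: int):
        if k in seed_cache:
            return seed_cache[k]
        idx: dict[str, list[tuple[str, str, int]]] = {}
        for f in fragments:
            for strand in "+-":
                seq = f.seq if strand == "+" else revcomp(f.seq)
                for i in range(len(seq) - k + 1):
                    idx.setdefault(seq[i : i + k], []).append((f.id, strand, i))
        seed_cache[k] = idx
        return idx

    for read in reads:
        seq = read.seq if isinstance(read.seq, str) else str(read.seq)
        L = len(seq)
        if L == 0:
            unmapped += 1
            continue
        k = max(1, L // (max_mismatch + 1))
        idx = seed_index(k)
        rarr = np.frombuffer(seq.encode(), dtype=np.uint8)
        best = None  # (mismatches, fragment id, strand rank, position)
        seen: set[tuple[str, str, int]] = set()
        for chunk in range(max_mismatch + 1):
            off = chunk * k
            if off + k > L:
                break
            for fid, strand, pos in idx.get(seq[off : off + k], ()):
                start = pos - off
                farr = frag_arrays[fid][strand]
                if start < 0 or start + L > len(farr):
                    continue
                key = (fid, strand, start)
                if key in seen:
                    continue
                seen.add(key)
                mism = int((farr[start : start + L] != rarr).sum())
                if mism > max_mismatch:
                    continue
                # report position on the forward strand for determinism
                fwd_pos = start if strand == "+" else len(farr) - (start + L)
                cand = (mism, fid, 0 if strand == "+" else 1, fwd_pos)
                if best is None or cand < best:
                    best = cand
        if best is None:
            unmapped += 1
        else:
            counts[best[1]] += 1
    return counts, unmapped


@dataclass
class CoverageSummary:
    """Per-fragment coverage table plus totals and unweighted means."""

    table: pd.DataFrame  # fragment, length_bp, n_cds, reads_mapped, bases_mapped, coverage
    total_length: int
    total_reads: int
    total_bases: int
    mean_coverage: float

    def to_tsv(self, path) -> None:
        df = self.table.copy()
        totals = {
            "fragment": "Total",
            "length_bp": self.total_length,
            "reads_mapped": self.total_reads,
            "bases_mapped": self.total_bases,
        }
        avg = {"fragment": "Average", "coverage": self.mean_coverage}
        df = pd.concat(
            [df, pd.DataFrame([totals]), pd.DataFrame([avg])], ignore_index=True
        )
        df.to_csv(path, sep="\t", index=False)


def coverage_table(counts: dict[str, int], lengths: dict[str, int],
                   read_length: int = 100,
                   n_cds: dict[str, int] | None = None) -> CoverageSummary:
    """Build the per-fragment read-coverage summary.

    bases = reads x read_length; coverage = bases / length rounded half-up
    to 1 decimal; totals are exact column sums; mean coverage is the
    unweighted mean of the per-fragment (rounded) coverages.
    """
    if set(counts) != set(lengths):
        raise ValueError("counts and lengths must cover the same fragments")
    rows = []
    for fid in lengths:
        if lengths[fid] <= 0:
            raise ValueError(f"fragment {fid!r} has non-positive length")
        bases = counts[fid] * read_length
        cov = _round_half_up(bases / lengths[fid], 1)
        rows.append(
            {
                "fragment": fid,
                "length_bp": lengths[fid],
                "n_cds": (n_cds or {}).get(fid),
                "reads_mapped": counts[fid],
                "bases_mapped": bases,
                "coverage": cov,
            }
        )
    df = pd.DataFrame(rows)
    mean_cov = _round_half_up(float(df["coverage"].mean()), 1) if rows else 0.0
    return CoverageSummary(
        table=df,
        total_length=int(df["length_bp"].sum()) if rows else 0,
        total_reads=int(df["reads_mapped"].sum()) if rows else 0,
        total_bases=int(df["bases_mapped"].sum()) if rows else 0,
        mean_coverage=mean_cov,
    )


def unweighted_mean_gc(values) -> float:
    """Unweighted mean of per-fragment GC percentages, half-up to 3
    decimals — the convention behind the published summary table."""
    return _round_half_up(float(np.mean(list(values))), 3)


def gc_summary(fragments: list[SequenceRecord]
               ) -> tuple[dict[str, float | None], float | None]:
    """Per-fragment GC%% (2 decimals) and the unweighted mean (3 decimals).

    GC%% = 100*(G+C)/(A+C+G+T); ambiguous bases are excluded from the
    denominator. An all-ambiguous fragment reports None and is excluded
    from the mean.
    """
    per: dict[str, float | None] = {}
    vals = []
    for f in fragments:
        gc = sum(f.seq.count(b) for b in "GC")
        at = sum(f.seq.count(b) for b in "AT")
        if gc + at == 0:
            per[f.id] = None
            continue
        pct = _round_half_up(100.0 * gc / (gc + at), 2)
        per[f.id] = pct
        vals.append(pct)
    mean = unweighted_mean_gc(vals) if vals else None
    return per, mean


def n50(lengths) -> int:
    """Largest L such that contigs of length >= L sum to >= half the total."""
    lengths = sorted(int(x) for x in lengths)
    if not lengths or lengths[0] <= 0:
        raise ValueError("n50 requires non-empty positive lengths")
    half = sum(lengths) / 2
    acc = 0
    for L in reversed(lengths):
        acc += L
        if acc >= half:
            return L
    return lengths[0]  # pragma: no cover


@dataclass
class CoreGeneChecklist:
    """Presence/absence of each configured core gene in the annotation."""

    status: dict[str, dict]  # gene -> {present, partial, orfs}
    n_present: int

    def to_tsv(self, path) -> None:
        rows = [
            {
                "gene": g,
                "present": int(info["present"]),
                "partial": int(info["partial"]),
                "orfs": ",".join(info["orfs"]),
            }
            for g, info in self.status.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def core_gene_checklist(annotations, core_gene_list: list[str]
                        ) -> CoreGeneChecklist:
    """Check which core genes have >= 1 annotated ORF.

    Multiple ORFs annotated to the same core gene (e.g. a gene split across
    two fragments) collapse to a single presence; the gene is marked partial
    when every supporting ORF is itself partial.
    """
    status: dict[str, dict] = {}
    by_gene: dict[str, list] = {}
    for ann in annotations:
        if ann.hit is not None and ann.gene_name:
            by_gene.setdefault(ann.gene_name, []).append(ann)
    for gene in core_gene_list:
        anns = by_gene.get(gene, [])
        present = len(anns) > 0
        partial = present and all(
            a.orf.partial5 or a.orf.partial3 or a.partial_by_coverage
            for a in anns
        )
        status[gene] = {
            "present": present,
            "partial": partial,
            "orfs": [a.orf.name for a in anns],
        }
    return CoreGeneChecklist(status, sum(1 for v in status.values() if v["present"]))
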