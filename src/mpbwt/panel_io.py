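"""Reading and writing haplotype panels and match reports.

The canonical in-memory object is :class:`HaplotypePanel`: an ``M x N``
integer matrix of allele codes together with a per-site alphabet size
``t_k``.  Code 0 is the reference allele; codes ``1..t_k-1`` are the
alternate alleles at site ``k``.  Sites may have different alphabet sizes,
which is what makes the panel *multi-allelic*.

Supported on-disk formats:

* plain allele-matrix text — one haplotype per row, whitespace-separated
  non-negative integer codes;
* VCF with phased ``GT`` fields — each diploid sample contributes two
  haplotype rows (left of the phase separator first), allele code = VCF
  allele index, ``t_k = 1 + len(ALT)``;
* match-report TSV — ``hap_i  hap_j  start  end  length`` with a header
  line, intervals 0-based half-open.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import AlphabetViolationError, PanelFormatError

__all__ = [
    "HaplotypePanel",
    "read_matrix",
    "write_matrix",
    "read_vcf",
    "write_matches",
    "MATCH_HEADER",
]

MATCH_HEADER = "#hap_i\thap_j\tstart\tend\tlength"


@dataclasses.dataclass
class HaplotypePanel:
    """A phased haplotype panel of M sequences over N variant sites.

    Parameters
    ----------
    alleles
        ``(M, N)`` integer array; ``alleles[i, k]`` is the allele code of
        haplotype ``i`` at site ``k``.
    site_alphabet_sizes
        Length-``N`` array of per-site alphabet sizes ``t_k >= 1``.  Every
        code at site ``k`` must satisfy ``0 <= code < t_k``; the alphabet
        may exceed the observed codes but never be smaller.
    site_ids, sample_ids
        Optional labels (e.g. ``CHROM:POS`` for sites, haplotype names).
    """

    alleles: np.ndarray
    site_alphabet_sizes: np.ndarray
    site_ids: Optional[Sequence[str]] = None
    sample_ids: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.int32)
        if self.alleles.ndim != 2:
            raise PanelFormatError("allele matrix must be two-dimensional")
        if self.alleles.shape[0] < 1:
            raise PanelFormatError("panel must contain at least one haplotype")
        self.site_alphabet_sizes = np.asarray(self.site_alphabet_sizes, dtype=np.int32)
        if self.site_alphabet_sizes.shape != (self.alleles.shape[1],):
            raise PanelFormatError(
                "site_alphabet_sizes must have one entry per site"
            )
        if self.N and (self.site_alphabet_sizes < 1).any():
            raise PanelFormatError("every site alphabet size must be >= 1")
        if self.N and self.alleles.size:
            if self.alleles.min() < 0:
                raise AlphabetViolationError("negative allele code in panel")
            observed = self.alleles.max(axis=0)
            bad = np.nonzero(observed >= self.site_alphabet_sizes)[0]
            if bad.size:
                k = int(bad[0])
                raise AlphabetViolationError(
                    f"site {k}: allele code {int(observed[k])} exceeds "
                    f"alphabet size {int(self.site_alphabet_sizes[k])}"
                )

    @property
    def M(self) -> int:
        """Number of haplotypes."""
        return self.alleles.shape[0]

    @property
    def N(self) -> int:
        """Number of variant sites."""
        return self.alleles.shape[1]

    @property
    def max_alphabet_size(self) -> int:
        """Global t: the largest per-site alphabet size (0 for empty panels)."""
        return int(self.site_alphabet_sizes.max()) if self.N else 0

    def column(self, k: int) -> np.ndarray:
        """Allele codes of all haplotypes at site ``k`` (a view)."""
        return self.alleles[:, k]


def _observed_alphabet(alleles: np.ndarray) -> np.ndarray:
    if alleles.shape[1] == 0:
        return np.zeros(0, dtype=np.int32)
    return (alleles.max(axis=0) + 1).astype(np.int32)


def panel_from_matrix(
    alleles: np.ndarray, alphabet_size: Optional[int] = None
) -> HaplotypePanel:
    """Wrap a raw integer matrix as a panel.

    With ``alphabet_size=None`` (observed mode) each site's alphabet is
    ``1 + max`` of the codes seen there; with a fixed ``alphabet_size=t``
    every site gets ``t_k = t`` and any code ``>= t`` is an error.
    """
    alleles = np.ascontiguousarray(alleles, dtype=np.int32)
    if alphabet_size is None:
        sizes = _observed_alphabet(alleles)
    else:
        if alphabet_size < 1:
            raise PanelFormatError("fixed alphabet size must be >= 1")
        sizes = np.full(alleles.shape[1], alphabet_size, dtype=np.int32)
    return HaplotypePanel(alleles=alleles, site_alphabet_sizes=sizes)


def read_matrix(path, alphabet_size: Optional[int] = None) -> HaplotypePanel:
    """Read a plain-text allele matrix.

    The file holds M lines of N whitespace-separated non-negative integers.
    Blank lines and lines starting with ``#`` are ignored.  See
    :func:`panel_from_matrix` for the alphabet modes.
    """
    path = Path(path)
    rows: list[list[int]] = []
    width: Optional[int] = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            try:
                row = [int(tok) for tok in tokens]
            except ValueError as exc:
                raise PanelFormatError(
                    f"{path}:{lineno}: non-integer allele token"
                ) from exc
            if any(v < 0 for v in row):
                raise PanelFormatError(
                    f"{path}:{lineno}: negative allele code"
                )
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise PanelFormatError(
                    f"{path}:{lineno}: ragged row ({len(row)} sites, "
                    f"expected {width})"
                )
            rows.append(row)
    if not rows:
        raise PanelFormatError(f"{path}: empty panel (no haplotype rows)")
    alleles = np.array(rows, dtype=np.int32)
    return panel_from_matrix(alleles, alphabet_size=alphabet_size)


def write_matrix(panel: HaplotypePanel, path) -> None:
    """Write a panel in the plain allele-matrix text format."""
    path = Path(path)
    with path.open("w") as fh:
        for i in range(panel.M):
            fh.write(" ".join(str(int(v)) for v in panel.alleles[i]))
            fh.write("\n")


def _parse_region(region: str):
    chrom, _, rng = region.partition(":")
    if not rng:
        return chrom, None, None
    start_s, _, end_s = rng.partition("-")
    start = int(start_s.replace(",", "")) if start_s else None
    end = int(end_s.replace(",", "")) if end_s else None
    return chrom, start, end


def read_vcf(
    path,
    region: Optional[str] = None,
    missing_policy: str = "reject",
) -> HaplotypePanel:
    """Read phased genotypes from a VCF into a haplotype panel.

    Each diploid sample contributes two rows, left of the ``|`` separator
    first.  Allele code is the VCF allele index (0 = REF, j = j-th ALT) and
    ``t_k = 1 + len(ALT)``.  Multi-allelic records are kept as-is; they are
    the reason this reader exists.

    ``missing_policy`` controls ``.`` alleles: ``"reject"`` (default) raises
    naming the offending record, ``"extra_allele"`` codes the missing value
    as ``t_k`` and grows that site's alphabet by one.  Unphased heterozygous
    genotypes and half-calls are always rejected: the transform is defined
    on haplotypes, not genotypes.
    """
    from cyvcf2 import VCF  # deferred: htslib init is not free

    if missing_policy not in ("reject", "extra_allele"):
        raise PanelFormatError(f"unknown missing_policy {missing_policy!r}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise PanelFormatError(f"{path}: VCF has no samples")
    want_chrom = want_start = want_end = None
    if region is not None:
        want_chrom, want_start, want_end = _parse_region(region)

    columns: list[np.ndarray] = []
    sizes: list[int] = []
    site_ids: list[str] = []
    for var in vcf:
        if want_chrom is not None:
            if var.CHROM != want_chrom:
                continue
            if want_start is not None and var.POS < want_start:
                continue
            if want_end is not None and var.POS > want_end:
                continue
        t_k = 1 + len(var.ALT)
        label = f"{var.CHROM}:{var.POS}"
        col = np.empty(2 * len(samples), dtype=np.int32)
        has_missing = False
        for s, gt in enumerate(var.genotypes):
            # cyvcf2 genotype entry: [allele_a, allele_b, phased] (diploid)
            if len(gt) != 3:
                raise PanelFormatError(
                    f"{path}: {label}: sample {samples[s]} is not diploid"
                )
            left, right, phased = int(gt[0]), int(gt[1]), bool(gt[2])
            n_missing = (left < 0) + (right < 0)
            if n_missing == 1:
                raise PanelFormatError(
                    f"{path}: {label}: half-call for sample {samples[s]}"
                )
            if n_missing == 2:
                if missing_policy == "reject":
                    raise PanelFormatError(
                        f"{path}: {label}: missing genotype for sample "
                        f"{samples[s]} (missing_policy=reject)"
                    )
                left = right = t_k
                has_missing = True
            else:
                if not phased and left != right:
                    raise PanelFormatError(
                        f"{path}: {label}: unphased heterozygote for sample "
                        f"{samples[s]}; mpbwt requires phased haplotypes"
                    )
                if max(left, right) >= t_k:
                    raise PanelFormatError(
                        f"{path}: {label}: allele index {max(left, right)} "
                        f"exceeds ALT count {t_k - 1}"
                    )
            col[2 * s] = left
            col[2 * s + 1] = right
        columns.append(col)
        sizes.append(t_k + 1 if has_missing else t_k)
        site_ids.append(label)
    if not columns:
        raise PanelFormatError(f"{path}: no variant records retained")
    alleles = np.stack(columns, axis=1)
    sample_ids = [
        f"{name}_{h}" for name in samples for h in (0, 1)
    ]
    return HaplotypePanel(
        alleles=alleles,
        site_alphabet_sizes=np.array(sizes, dtype=np.int32),
        site_ids=site_ids,
        sample_ids=sample_ids,
    )


def write_matches(records: Iterable, path) -> None:
    """Write match records as a sorted TSV report.

    Each record is ``(hap_i, hap_j, start, end)`` with a 0-based half-open
    site interval; the written line appends ``length = end - start``.
    Output order is deterministic: sorted by end, start, hap_i, hap_j.
    """
    recs = sorted(
        (int(r[0]), int(r[1]), int(r[2]), int(r[3])) for r in records
    )
    recs.sort(key=lambda r: (r[3], r[2], r[0], r[1]))
    path = Path(path)
    with path.open("w") as fh:
        fh.write(MATCH_HEADER + "\n")
        for hi, hj, start, end in recs:
            fh.write(f"{hi}\t{hj}\t{start}\t{end}\t{end - start}\n")
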