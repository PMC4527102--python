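"""Result serialization: results TSV, Venn summary JSON, gene lists, run log.

Formatting follows spectral-counting reporting conventions: SpI and R_SC
to three decimals, p-values in scientific notation with three significant
digits.  All writers are deterministic — identical inputs yield
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

from .count_data import VennPartition
from .stats import LABEL_CASE, LABEL_CONTROL, LABEL_NS, DiffExprRecord, Thresholds

SPI_FORMULA = (
    "SpI = (d_B/N_B)*(n_B/(n_A+n_B)) - (d_A/N_A)*(n_A/(n_A+n_B))"
)

RESULTS_COLUMNS = [
    "entry_name", "gene_id", "description", "length_aa",
    "d_A", "d_B", "n_A", "n_B",
    "p_g", "spi", "rsc", "p_fisher", "p_mw",
    "label", "top_tier", "spi_flag", "bh_fdr",
]


def _fmt_p(p: float | None) -> str:
    return "" if p is None else f"{p:.3E}"


def _fmt3(x: float | None) -> str:
    return "" if x is None else f"{x:.3f}"


def write_results_tsv(records: Sequence[DiffExprRecord], path: str | Path) -> None:
    """Write one row per record in the order given (descending SpI when
    the records come from ``run_differential_table``)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(RESULTS_COLUMNS) + "\n")
        for r in records:
            p, s = r.protein, r.summary
            cells = [
                p.entry_name, p.gene_id, p.description,
                "" if p.length_aa is None else str(p.length_aa),
                str(s.d_a), str(s.d_b), str(s.n_a), str(s.n_b),
                _fmt_p(r.p_g), _fmt3(r.spi), _fmt3(r.rsc),
                _fmt_p(r.p_fisher), _fmt_p(r.p_mw),
                r.label, str(int(r.top_tier)), str(int(r.spi_flag)),
                _fmt_p(r.bh_fdr),
            ]
            fh.write("\t".join(cells) + "\n")


def write_venn_json(partition: VennPartition, path: str | Path) -> None:
    payload = {
        "sizes": partition.sizes,
        "members": {
            "unique_to_a": list(partition.unique_to_a),
            "shared": list(partition.shared),
            "unique_to_b": list(partition.unique_to_b),
        },
        "never_observed": list(partition.never_observed),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def write_gene_lists(records: Sequence[DiffExprRecord], out_dir: str | Path) -> dict[str, Path]:
    """One plain-text gene list per label class, for submission to
    external enrichment/network services.  Gene ids fall back to entry
    names; duplicates are dropped, record order kept."""
    out_dir = Path(out_dir)
    paths: dict[str, Path] = {}
    for label in (LABEL_CASE, LABEL_CONTROL, LABEL_NS):
        genes: list[str] = []
        for r in records:
            if r.label != label:
                continue
            g = r.protein.gene_id or r.protein.entry_name
            if g not in genes:
                genes.append(g)
        path = out_dir / f"genes_{label}.txt"
        path.write_text("".join(f"{g}\n" for g in genes), encoding="utf-8")
        paths[label] = path
    return paths


def write_run_log(
    records: Sequence[DiffExprRecord],
    thresholds: Thresholds,
    detection_threshold: int,
    path: str | Path,
) -> None:
    """Self-describing run log: formula, thresholds, class sizes, and
    every skipped protein with its reason.  No timestamps, so repeated
    runs on identical inputs produce identical logs."""
    lines = [
        "spcdiff run log",
        f"spectral index formula: {SPI_FORMULA}",
        f"thresholds: alpha_g={thresholds.alpha_g} rsc_cut={thresholds.rsc_cut} "
        f"spi_cut={thresholds.spi_cut} alpha_top={thresholds.alpha_top} "
        f"rsc_top={thresholds.rsc_top} f={thresholds.f}",
        f"detection_threshold: {detection_threshold}",
        f"proteins: {len(records)}",
    ]
    for label in (LABEL_CASE, LABEL_CONTROL, LABEL_NS):
        n = sum(r.label == label for r in records)
        lines.append(f"label {label}: {n}")
    lines.append(f"top_tier: {sum(r.top_tier for r in records)}")
    skipped = [r for r in records if r.skip_reason]
    lines.append(f"skipped: {len(skipped)}")
    for r in skipped:
        lines.append(f"skipped {r.entry_name}: {r.skip_reason}")
    Path(path).write_text("".join(f"{ln}\n" for ln in lines), encoding="utf-8")
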