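"""Built-in gene locus registry.

GRCh38 coordinates (1-based, closed intervals) for the three NTRK receptor
kinase genes and the seven recurrent 5' fusion partners of NTRK3 interrogated
by the cryptic-fusion score. The registry is plain data: callers may replace
or extend it (e.g. via :func:`load_registry`) without touching code.
"""

from __future__ import annotations

from .io_formats import GeneLocus

#: NTRK3 5' fusion partner symbols, in no particular order.
PARTNER_GENES = ("ETV6", "TPM3", "TPR", "SQSTM1", "EML4", "MYH9", "MYO5A")

#: ETV6 is still widely reported under its historical symbol TEL.
GENE_ALIASES = {"TEL": "ETV6"}

DEFAULT_REGISTRY = {
    "NTRK1": GeneLocus("NTRK1", "1", 156_815_640, 156_881_850, "+"),
    "NTRK2": GeneLocus("NTRK2", "9", 84_665_760, 85_030_334, "+"),
    "NTRK3": GeneLocus("NTRK3", "15", 87_859_751, 88_256_768, "-"),
    "ETV6": GeneLocus("ETV6", "12", 11_649_601, 11_895_377, "+"),
    "TPM3": GeneLocus("TPM3", "1", 154_155_308, 154_192_100, "-"),
    "TPR": GeneLocus("TPR", "1", 186_311_035, 186_375_690, "-"),
    "SQSTM1": GeneLocus("SQSTM1", "5", 179_806_398, 179_838_078, "+"),
    "EML4": GeneLocus("EML4", "2", 42_169_353, 42_332_548, "+"),
    "MYH9": GeneLocus("MYH9", "22", 36_281_280, 36_388_067, "-"),
    "MYO5A": GeneLocus("MYO5A", "15", 52_307_290, 52_529_050, "-"),
}


def resolve_symbol(symbol: str) -> str:
    """Normalize a gene symbol: trim, upper-case, resolve known aliases."""
    sym = symbol.strip().upper()
    return GENE_ALIASES.get(sym, sym)


def load_registry(path) -> dict[str, GeneLocus]:
    """Read a user registry from a TSV with columns symbol, chromosome, start, end, strand."""
    import pandas as pd

    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"symbol", "chromosome", "start", "end", "strand"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"registry file missing columns: {sorted(missing)}")
    registry = {}
    for _, row in table.iterrows():
        sym = resolve_symbol(row["symbol"])
        registry[sym] = GeneLocus(
            sym, str(row["chromosome"]), int(row["start"]), int(row["end"]), row["strand"]
        )
    return registry
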