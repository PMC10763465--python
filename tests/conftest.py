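import pytest

from dass import RawTable, TEMPLATE_HEADER


def make_table(rows: list[dict[str, str]], header=TEMPLATE_HEADER) -> RawTable:
    """Build a canonical-template RawTable from per-row {column: text} dicts."""
    grid = [[row.get(col, "") for col in header] for row in rows]
    return RawTable(header=list(header), rows=grid, source_format="tsv")


@pytest.fixture
def small_table() -> RawTable:
    return make_table([
        {"chem_id": "A", "dpra_cys_pct": "30", "dpra_lys_pct": "10", "hclat_mit": "negative",
         "ks_call": "p", "insilico_call": "n", "insilico_domain": "in"},
        {"chem_id": "B", "dpra_cys_pct": "80", "dpra_lys_pct": "60", "hclat_mit": "5",
         "ks_call": "positive", "insilico_call": "positive", "insilico_domain": "in"},
        {"chem_id": "C"},
    ])
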