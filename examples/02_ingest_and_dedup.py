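"""Ingest FAERS-format quarterly files and deduplicate case versions.

Every line of every file is accounted for (accepted or rejected with a
reason), and deduplication keeps one survivor per case — the most recent
version by receipt date, follow-up status, event date, then primaryid.

Run examples/01_simulate_snapshot.py first (or point at real FAERS files).
"""

from pathlib import Path

from faerspv import deduplicate, discover_quarters, read_quarters
from faerspv.ingest import load_log_frame

snapshot = Path("scratch/example_snapshot")
if not snapshot.exists():
    raise SystemExit("run examples/01_simulate_snapshot.py first")

file_sets = discover_quarters(snapshot)
tables, logs = read_quarters(file_sets)
print(load_log_frame(logs).to_string(index=False))
print(f"\njoined {tables.n_reports} raw reports; orphan child rows: {tables.orphans}")

result = deduplicate(tables)
print(f"deduplicated: {tables.n_reports} reports -> {result.tables.n_reports} cases "
      f"({result.n_removed} superseded versions removed)")
print("\nfirst dedup-log entries (removed version -> surviving version):")
print(result.log.head(5).to_string(index=False))
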