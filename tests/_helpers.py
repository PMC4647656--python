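"""Shared test helpers."""

import tempfile
from pathlib import Path


def records_from_lines(sam_lines):
    """Parse SAM text lines through the package reader via a temp file."""
    from rdipkit.genome_io import read_sam_records

    with tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False) as handle:
        handle.write("\n".join(sam_lines) + "\n")
        path = handle.name
    try:
        yield from read_sam_records(path)
    finally:
        Path(path).unlink(missing_ok=True)
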