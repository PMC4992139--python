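"""Helper for the deposited-coordinate checks.

The deposited baseplate ensemble (PDB entry 5LCB) is not bundled with the
package.  Place the PDB-format file at ``data/5LCB.pdb`` (repository root)
or let the helper try to download it; in an offline environment without
the file the acceptance checks that need it fail with this explanation.
"""

from pathlib import Path

DEPOSITED_ID = "5LCB"
SEARCH_PATHS = [
    Path(__file__).resolve().parent.parent / "data" / "5LCB.pdb",
    Path("data/5LCB.pdb"),
]
_URL = "https://files.rcsb.org/download/5LCB.pdb"


def deposited_structure_path() -> Path:
    for p in SEARCH_PATHS:
        if p.exists():
            return p
    target = SEARCH_PATHS[0]
    try:
        import urllib.request
        target.parent.mkdir(parents=True, exist_ok=True)
        with urllib.request.urlopen(_URL, timeout=10) as resp:  # noqa: S310
            data = resp.read()
        target.write_bytes(data)
        return target
    except Exception as exc:
        raise FileNotFoundError(
            f"deposited ensemble {DEPOSITED_ID} unavailable: not found at "
            f"{[str(p) for p in SEARCH_PATHS]} and download failed ({exc}). "
            "Provide data/5LCB.pdb to run the deposited-coordinate checks."
        ) from exc
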