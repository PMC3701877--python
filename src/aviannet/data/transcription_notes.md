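# Transcription notes for `pigeon_table2.txt`

The connection table is frozen verbatim from the published meta-analysis
table (52 regions, 344 directed connections after parsing). The following
typographic irregularities are present in the source and are preserved in
the data file rather than silently corrected; the parser resolves each as an
edge statement only, and all citation indices are discarded.

1. Row `CPi`, statement `← NSTL: 1. 9, 23, 29` — the citation list contains
   a period where a comma is expected ("1. 9"). Citations carry no graph
   information; the statement parses as the single edge NSTL → CPi.
2. Row `Ei`, statement `Ei → MVL: 5, 12, 20, 24` — the row label is
   duplicated inside the statement. Parsed as `→ MVL`, i.e. Ei → MVL.
3. Rows `L1`/`L2` contain statements with missing spaces around arrows
   (`←MC: 5`, `→NCL: 19, 33`). Parsed normally.
4. Rows `AD`, `CDL`, `L1`, `HL` end with a dangling semicolon; empty
   statements are skipped.
5. The sources `Field L1`, `Field L2`, `Field L3` appearing as targets are
   normalized to the row labels `L1`, `L2`, `L3` used elsewhere.
6. Row `AD` lists `→ StL` but `← StM` (compare rows AA and AI which list
   `→ StL; → StM` with identical citations). Transcribed exactly as
   printed: the edge is StM → AD.

Independent checks of the frozen transcription (enforced by the test
suite): 344 edges over exactly the 52 registry regions; no self-loops; no
isolated region; BO has out-degree 6 and in-degree 0; AD, AI and NCL form a
complete directed subgraph.
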