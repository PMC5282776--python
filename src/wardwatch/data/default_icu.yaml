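associate_radius_m: 1.5
beacons:
- beacon_id: B-R1-BED1
  facility_id: R1-BED1
  range_m: 3.0
- beacon_id: B-R1-DISP-BED1
  facility_id: R1-DISP-BED1
  range_m: 1.5
- beacon_id: B-R1-BED2
  facility_id: R1-BED2
  range_m: 3.0
- beacon_id: B-R1-DISP-BED2
  facility_id: R1-DISP-BED2
  range_m: 1.5
- beacon_id: B-R1-BED3
  facility_id: R1-BED3
  range_m: 3.0
- beacon_id: B-R1-DISP-BED3
  facility_id: R1-DISP-BED3
  range_m: 1.5
- beacon_id: B-R1-BED4
  facility_id: R1-BED4
  range_m: 3.0
- beacon_id: B-R1-DISP-BED4
  facility_id: R1-DISP-BED4
  range_m: 1.5
- beacon_id: B-R1-DISP-DOOR
  facility_id: R1-DISP-DOOR
  range_m: 1.5
- beacon_id: B-R1-SINK
  facility_id: R1-SINK
  range_m: 1.5
- beacon_id: B-R1-CENTRAL
  facility_id: R1-CENTRAL
  range_m: 4.0
- beacon_id: B-R2-BED1
  facility_id: R2-BED1
  range_m: 3.0
- beacon_id: B-R2-DISP-BED1
  facility_id: R2-DISP-BED1
  range_m: 1.5
- beacon_id: B-R2-BED2
  facility_id: R2-BED2
  range_m: 3.0
- beacon_id: B-R2-DISP-BED2
  facility_id: R2-DISP-BED2
  range_m: 1.5
- beacon_id: B-R2-DISP-DOOR
  facility_id: R2-DISP-DOOR
  range_m: 1.5
- beacon_id: B-R2-SINK
  facility_id: R2-SINK
  range_m: 1.5
- beacon_id: B-R2-CENTRAL
  facility_id: R2-CENTRAL
  range_m: 4.0
- beacon_id: B-R3-BED1
  facility_id: R3-BED1
  range_m: 3.0
- beacon_id: B-R3-DISP-BED1
  facility_id: R3-DISP-BED1
  range_m: 1.5
- beacon_id: B-R3-BED2
  facility_id: R3-BED2
  range_m: 3.0
- beacon_id: B-R3-DISP-BED2
  facility_id: R3-DISP-BED2
  range_m: 1.5
- beacon_id: B-R3-DISP-DOOR
  facility_id: R3-DISP-DOOR
  range_m: 1.5
- beacon_id: B-R3-SINK
  facility_id: R3-SINK
  range_m: 1.5
- beacon_id: B-R3-CENTRAL
  facility_id: R3-CENTRAL
  range_m: 4.0
facilities:
- id: R1-BED1
  kind: BED
  position:
  - 1.0
  - 5.0
  room_id: R1
- id: R1-DISP-BED1
  kind: DISPENSER
  position:
  - 1.0
  - 4.0
  room_id: R1
- id: R1-BED2
  kind: BED
  position:
  - 3.0
  - 5.0
  room_id: R1
- id: R1-DISP-BED2
  kind: DISPENSER
  position:
  - 3.0
  - 4.0
  room_id: R1
- id: R1-BED3
  kind: BED
  position:
  - 5.0
  - 5.0
  room_id: R1
- id: R1-DISP-BED3
  kind: DISPENSER
  position:
  - 5.0
  - 4.0
  room_id: R1
- id: R1-BED4
  kind: BED
  position:
  - 7.0
  - 5.0
  room_id: R1
- id: R1-DISP-BED4
  kind: DISPENSER
  position:
  - 7.0
  - 4.0
  room_id: R1
- id: R1-DISP-DOOR
  kind: DISPENSER
  position:
  - 0.5
  - 0.5
  room_id: R1
- id: R1-SINK
  kind: SINK
  position:
  - 7.0
  - 0.5
  room_id: R1
- id: R1-CENTRAL
  kind: CENTRAL
  position:
  - 4.0
  - 2.5
  room_id: R1
- id: R2-BED1
  kind: BED
  position:
  - 1.5
  - 5.0
  room_id: R2
- id: R2-DISP-BED1
  kind: DISPENSER
  position:
  - 1.5
  - 4.0
  room_id: R2
- id: R2-BED2
  kind: BED
  position:
  - 3.5
  - 5.0
  room_id: R2
- id: R2-DISP-BED2
  kind: DISPENSER
  position:
  - 3.5
  - 4.0
  room_id: R2
- id: R2-DISP-DOOR
  kind: DISPENSER
  position:
  - 0.5
  - 0.5
  room_id: R2
- id: R2-SINK
  kind: SINK
  position:
  - 4.0
  - 0.5
  room_id: R2
- id: R2-CENTRAL
  kind: CENTRAL
  position:
  - 2.5
  - 2.5
  room_id: R2
- id: R3-BED1
  kind: BED
  position:
  - 1.5
  - 5.0
  room_id: R3
- id: R3-DISP-BED1
  kind: DISPENSER
  position:
  - 1.5
  - 4.0
  room_id: R3
- id: R3-BED2
  kind: BED
  position:
  - 3.5
  - 5.0
  room_id: R3
- id: R3-DISP-BED2
  kind: DISPENSER
  position:
  - 3.5
  - 4.0
  room_id: R3
- id: R3-DISP-DOOR
  kind: DISPENSER
  position:
  - 0.5
  - 0.5
  room_id: R3
- id: R3-SINK
  kind: SINK
  position:
  - 4.0
  - 0.5
  room_id: R3
- id: R3-CENTRAL
  kind: CENTRAL
  position:
  - 2.5
  - 2.5
  room_id: R3
rooms:
- height_m: 6.0
  id: R1
  origin:
  - 0.0
  - 0.0
  width_m: 8.0
- height_m: 6.0
  id: R2
  origin:
  - 9.0
  - 0.0
  width_m: 5.0
- height_m: 6.0
  id: R3
  origin:
  - 15.0
  - 0.0
  width_m: 5.0
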