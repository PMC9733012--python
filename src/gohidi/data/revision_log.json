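[
 {
  "kind": "add",
  "code": "1.2.6",
  "name": "COVID-19"
 },
 {
  "kind": "delete",
  "targets": [
   "1.2.4",
   "1.4.4",
   "1.7.1",
   "1.7.2",
   "1.7.3",
   "2.2.3",
   "2.2.4",
   "2.2.5",
   "2.2.6",
   "2.2.7",
   "2.2.8",
   "2.2.9",
   "2.2.10",
   "2.6.1",
   "2.4.7",
   "2.4.8",
   "2.6.2",
   "3.6.4",
   "2.5.1"
  ]
 },
 {
  "kind": "merge",
  "targets": [
   "3.1",
   "3.2"
  ],
  "code": "3.1",
  "name": "Air Quality and Climate Change"
 },
 {
  "kind": "delete",
  "targets": [
   "1.7",
   "2.5",
   "2.6"
  ]
 },
 {
  "kind": "rename",
  "targets": [
   "3.3"
  ],
  "name": "Land Resources"
 },
 {
  "kind": "rename",
  "targets": [
   "3.5"
  ],
  "name": "Hazardous Chemicals"
 },
 {
  "kind": "rename",
  "targets": [
   "2.3"
  ],
  "name": "Animal Nutritional Status"
 }
]
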