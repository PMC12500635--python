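item_id,label,dimension
A1,Exercise,Safety and health requirements
A2,Rehabilitation training,Safety and health requirements
A3,In-home medical service,Safety and health requirements
A4,Telemedicine,Safety and health requirements
A5,Taking medicine,Safety and health requirements
A6,Boiling traditional Chinese medicine,Safety and health requirements
A7,Caring for the sick,Safety and health requirements
B1,Cooking,Life requirements
B2,Food distribution,Life requirements
B3,Hair cutting,Life requirements
B4,Travelling,Life requirements
B5,Brushing teeth,Life requirements
B6,Washing hair,Life requirements
B7,Bathing,Life requirements
B8,Cleaning,Life requirements
B9,Repairing household appliances,Life requirements
B10,Pest controlling,Life requirements
B11,Finding items,Life requirements
B12,Pick up express,Life requirements
B13,Mowing the lawn,Life requirements
B14,Walking the dog,Life requirements
B15,Feeding birds,Life requirements
B16,Purchasing living goods,Life requirements
B17,Legal consulting,Life requirements
C1,Tea party for older adults,Learning and social needs
C2,Cooking competition,Learning and social needs
C3,Foreign language learning,Learning and social needs
C4,Sightseeing,Learning and social needs
C5,Party dating,Learning and social needs
C6,Red Song Club,Learning and social needs
C7,Life skills learning,Learning and social needs
C8,Instructions for using electronic products,Learning and social needs
C9,Learning craft making,Learning and social needs
D1,Chatting,Spiritual needs
D2,Psychological counselling,Spiritual needs
D3,Listening to music,Spiritual needs
D4,Watching movies,Spiritual needs
D5,Voluntary activities,Spiritual needs
E1,Practicing calligraphy,Entertainment needs
E2,Square dancing,Entertainment needs
E3,Going to the park,Entertainment needs
E4,Practicing Tai chi,Entertainment needs
E5,Learning musical instruments,Entertainment needs
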