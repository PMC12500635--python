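dimension,item_no,label,item_id,attribute,better,worse
Safety and health requirements,1,Exercise,A1,O,70.04%,-66.67%
Safety and health requirements,2,Rehabilitation training,A2,O,60.00%,-57.08%
Safety and health requirements,3,In-home medical service,A3,A,55.23%,-28.03%
Safety and health requirements,4,Telemedicine,A4,A,54.20%,-29.41%
Safety and health requirements,5,Taking medicine,A5,I,20.34%,-28.81%
Safety and health requirements,6,Boiling traditional Chinese medicine,A6,O,60.67%,-61.92%
Safety and health requirements,7,Caring for the sick,A7,A,61.70%,-27.66%
Life requirements,1,Cooking,B1,M,32.08%,-55.83%
Life requirements,2,Food distribution,B2,I,25.21%,-26.50%
Life requirements,3,Hair cutting,B3,O,67.65%,-65.13%
Life requirements,4,Travelling,B4,O,71.73%,-64.56%
Life requirements,5,Brushing teeth,B5,I,25.83%,-31.25%
Life requirements,6,Washing hair,B6,M,29.11%,-59.92%
Life requirements,7,Bathing,B7,I,26.81%,-19.15%
Life requirements,8,Cleaning,B8,A,60.70%,-24.89%
Life requirements,9,Repairing household appliances,B9,A,55.02%,-35.37%
Life requirements,10,Pest controlling,B10,I,32.17%,-33.04%
Life requirements,11,Finding items,B11,A,55.88%,-33.19%
Life requirements,12,Pick up express,B12,A,54.27%,-32.48%
Life requirements,13,Mowing the lawn,B13,I,26.29%,-29.31%
Life requirements,14,Walking the dog,B14,M,31.65%,-54.01%
Life requirements,15,Feeding birds,B15,I,22.88%,-28.39%
Life requirements,16,Purchasing living goods,B16,I,23.83%,-31.49%
Life requirements,17,Legal consulting,B17,A,54.66%,-29.24%
Learning and social needs,1,Tea party for older adults,C1,M,23.93%,-61.54%
Learning and social needs,2,Cooking competition,C2,M,29.00%,-54.11%
Learning and social needs,3,Foreign language learning,C3,I,26.67%,-29.58%
Learning and social needs,4,Sightseeing,C4,M,34.18%,-55.27%
Learning and social needs,5,Party dating,C5,M,25.43%,-60.78%
Learning and social needs,6,Red Song Club,C6,A,67.93%,-18.57%
Learning and social needs,7,Life skills learning,C7,M,29.96%,-54.85%
Learning and social needs,8,Instructions for using electronic products,C8,O,59.31%,-57.58%
Learning and social needs,9,Learning craft making,C9,M,34.62%,-55.98%
Spiritual needs,1,Chatting,D1,M,24.89%,-63.32%
Spiritual needs,2,Psychological counselling,D2,O,65.53%,-63.83%
Spiritual needs,3,Listening to music,D3,M,28.94%,-61.28%
Spiritual needs,4,Watching movies,D4,M,27.12%,-59.32%
Spiritual needs,5,Voluntary activities,D5,M,32.91%,-56.41%
Entertainment needs,1,Practicing calligraphy,E1,A,56.25%,-29.58%
Entertainment needs,2,Square dancing,E2,M,28.45%,-61.64%
Entertainment needs,3,Going to the park,E3,M,34.93%,-48.47%
Entertainment needs,4,Practicing Tai chi,E4,M,26.78%,-58.58%
Entertainment needs,5,Learning musical instruments,E5,M,25.21%,-62.82%
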